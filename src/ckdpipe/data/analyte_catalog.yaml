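# Default canine analyte catalog: 35 routinely measured laboratory data types
# (clinical chemistry, hematology, urinalysis) with literature-typical adult
# canine reference intervals. Reference intervals vary by laboratory; this
# catalog is fully overridable via AnalyteCatalog.from_yaml.
creatinine:      {units: "mg/dL",    normal_low: 0.5,   normal_high: 1.8,   category: blood}
BUN:             {units: "mg/dL",    normal_low: 7.0,   normal_high: 27.0,  category: blood}
phosphorus:      {units: "mg/dL",    normal_low: 2.5,   normal_high: 6.8,   category: blood}
calcium:         {units: "mg/dL",    normal_low: 7.9,   normal_high: 12.0,  category: blood}
total_protein:   {units: "g/dL",     normal_low: 5.2,   normal_high: 8.2,   category: blood}
albumin:         {units: "g/dL",     normal_low: 2.3,   normal_high: 4.0,   category: blood}
globulin:        {units: "g/dL",     normal_low: 2.5,   normal_high: 4.5,   category: blood}
glucose:         {units: "mg/dL",    normal_low: 74.0,  normal_high: 143.0, category: blood}
ALT:             {units: "U/L",      normal_low: 10.0,  normal_high: 125.0, category: blood}
ALP:             {units: "U/L",      normal_low: 23.0,  normal_high: 212.0, category: blood}
AST:             {units: "U/L",      normal_low: 10.0,  normal_high: 50.0,  category: blood}
GGT:             {units: "U/L",      normal_low: 0.1,   normal_high: 11.0,  category: blood}
total_bilirubin: {units: "mg/dL",    normal_low: 0.01,  normal_high: 0.9,   category: blood}
cholesterol:     {units: "mg/dL",    normal_low: 110.0, normal_high: 320.0, category: blood}
triglycerides:   {units: "mg/dL",    normal_low: 20.0,  normal_high: 150.0, category: blood}
sodium:          {units: "mmol/L",   normal_low: 144.0, normal_high: 160.0, category: blood}
potassium:       {units: "mmol/L",   normal_low: 3.5,   normal_high: 5.8,   category: blood}
chloride:        {units: "mmol/L",   normal_low: 109.0, normal_high: 122.0, category: blood}
bicarbonate:     {units: "mmol/L",   normal_low: 17.0,  normal_high: 27.0,  category: blood}
amylase:         {units: "U/L",      normal_low: 500.0, normal_high: 1500.0, category: blood}
lipase:          {units: "U/L",      normal_low: 200.0, normal_high: 1800.0, category: blood}
hematocrit:      {units: "%",        normal_low: 37.0,  normal_high: 55.0,  category: blood}
hemoglobin:      {units: "g/dL",     normal_low: 12.0,  normal_high: 18.0,  category: blood}
RBC:             {units: "10^6/uL",  normal_low: 5.5,   normal_high: 8.5,   category: blood}
WBC:             {units: "10^3/uL",  normal_low: 6.0,   normal_high: 17.0,  category: blood}
neutrophils:     {units: "10^3/uL",  normal_low: 3.0,   normal_high: 11.5,  category: blood}
lymphocytes:     {units: "10^3/uL",  normal_low: 1.0,   normal_high: 4.8,   category: blood}
monocytes:       {units: "10^3/uL",  normal_low: 0.15,  normal_high: 1.35,  category: blood}
eosinophils:     {units: "10^3/uL",  normal_low: 0.1,   normal_high: 1.25,  category: blood}
platelets:       {units: "10^3/uL",  normal_low: 200.0, normal_high: 500.0, category: blood}
MCV:             {units: "fL",       normal_low: 60.0,  normal_high: 77.0,  category: blood}
USG:             {units: "unitless", normal_low: 1.015, normal_high: 1.060, category: urine}
urine_protein:   {units: "mg/dL",    normal_low: 0.0,   normal_high: 30.0,  category: urine}
urine_pH:        {units: "unitless", normal_low: 5.5,   normal_high: 7.5,   category: urine}
urine_glucose:   {units: "mg/dL",    normal_low: 0.0,   normal_high: 10.0,  category: urine}
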