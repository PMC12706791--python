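{
 "version": 1,
 "description": "Stylized xanthone scaffold used by the synthetic generator for non-diagnostic filler carbons: fixed base ppm per label, shared by all subtypes, jittered per compound. Synthetic scaffolding, not literature values.",
 "carbons": [
  {
   "label": "C-1",
   "ppm": 162.5,
   "carbon_class": "core_Cq"
  },
  {
   "label": "C-4a",
   "ppm": 164.0,
   "carbon_class": "core_Cq"
  },
  {
   "label": "C-5",
   "ppm": 108.2,
   "carbon_class": "core_CH"
  },
  {
   "label": "C-6",
   "ppm": 167.2,
   "carbon_class": "core_Cq"
  },
  {
   "label": "C-7",
   "ppm": 136.9,
   "carbon_class": "core_CH"
  },
  {
   "label": "C-8",
   "ppm": 111.0,
   "carbon_class": "core_CH"
  },
  {
   "label": "C-8a",
   "ppm": 111.9,
   "carbon_class": "core_Cq"
  },
  {
   "label": "C-9a",
   "ppm": 107.6,
   "carbon_class": "core_Cq"
  },
  {
   "label": "C-10a",
   "ppm": 165.6,
   "carbon_class": "core_Cq"
  },
  {
   "label": "C-3'",
   "ppm": 78.2,
   "carbon_class": "other"
  },
  {
   "label": "C-4'",
   "ppm": 28.4,
   "carbon_class": "methyl"
  },
  {
   "label": "C-5'",
   "ppm": 28.1,
   "carbon_class": "methyl"
  }
 ],
 "subtype_carbons": {
  "A20": [
   {
    "label": "C-1",
    "ppm": 110.8,
    "carbon_class": "core_Cq"
   }
  ],
  "A23": [
   {
    "label": "C-1",
    "ppm": 110.6,
    "carbon_class": "core_Cq"
   }
  ],
  "B13": [
   {
    "label": "C-2",
    "ppm": 109.8,
    "carbon_class": "core_Cq"
   }
  ],
  "B31": [
   {
    "label": "C-2",
    "ppm": 112.2,
    "carbon_class": "core_Cq"
   }
  ],
  "B34": [
   {
    "label": "C-2",
    "ppm": 111.4,
    "carbon_class": "core_Cq"
   }
  ],
  "C21": [
   {
    "label": "C-3",
    "ppm": 108.9,
    "carbon_class": "core_Cq"
   }
  ],
  "C24": [
   {
    "label": "C-3",
    "ppm": 109.4,
    "carbon_class": "core_Cq"
   }
  ],
  "C40": [
   {
    "label": "C-3",
    "ppm": 110.2,
    "carbon_class": "core_Cq"
   }
  ],
  "C41": [
   {
    "label": "C-3",
    "ppm": 111.8,
    "carbon_class": "core_Cq"
   }
  ],
  "D31": [
   {
    "label": "C-4",
    "ppm": 108.0,
    "carbon_class": "core_Cq"
   }
  ],
  "D32": [
   {
    "label": "C-4",
    "ppm": 109.0,
    "carbon_class": "core_Cq"
   }
  ]
 }
}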