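{
  "name": "Pharm-CAT v1",
  "items": [
    {
      "item_id": 1,
      "section": "study_design",
      "label": "Study phase",
      "levels": [
        {"score": 1, "description": "phase II or phase III"},
        {"score": 3, "description": "phase I"}
      ]
    },
    {
      "item_id": 2,
      "section": "study_design",
      "label": "Type of drug",
      "levels": [
        {"score": 2, "description": "oral drug"},
        {"score": 3, "description": "injectable drug"}
      ]
    },
    {
      "item_id": 3,
      "section": "study_design",
      "label": "Interactive web response systems (IWRSs)",
      "levels": [
        {"score": 1, "description": "consultation only (documentation and reporting)"},
        {"score": 2, "description": "supply chain management"},
        {"score": 3, "description": "treatment assignment"}
      ]
    },
    {
      "item_id": 4,
      "section": "study_design",
      "label": "Number of drugs involved",
      "levels": [
        {"score": 1, "description": "1 drug"},
        {"score": 2, "description": "2 drugs"},
        {"score": 3, "description": ">= 3 drugs"}
      ]
    },
    {
      "item_id": 5,
      "section": "study_design",
      "label": "Days of therapy per cycle",
      "levels": [
        {"score": 1, "description": "1 day"},
        {"score": 2, "description": "2 or 3 days"},
        {"score": 3, "description": ">= 4 days"}
      ]
    },
    {
      "item_id": 6,
      "section": "drug_management",
      "label": "Pharmacy staff",
      "levels": [
        {"score": 2, "description": "logistics operator + pharmacist"},
        {"score": 3, "description": "logistics operator + pharmacist + technical operator"}
      ]
    },
    {
      "item_id": 7,
      "section": "drug_management",
      "label": "Storage conditions",
      "levels": [
        {"score": 1, "description": "controlled room temperature or under refrigeration"},
        {"score": 2, "description": "controlled room temperature and under refrigeration"},
        {"score": 3, "description": "deep-freeze"}
      ]
    },
    {
      "item_id": 8,
      "section": "drug_management",
      "label": "Supply of special material/medical devices",
      "levels": [
        {"score": 1, "description": "no"},
        {"score": 2, "description": "yes"}
      ]
    },
    {
      "item_id": 9,
      "section": "drug_management",
      "label": "Relabelling of drugs not supplied",
      "levels": [
        {"score": 1, "description": "no"},
        {"score": 3, "description": "yes"}
      ]
    },
    {
      "item_id": 10,
      "section": "drug_management",
      "label": "Returned drug accountability",
      "levels": [
        {"score": 1, "description": "no"},
        {"score": 3, "description": "yes"}
      ]
    },
    {
      "item_id": 11,
      "section": "drug_management",
      "label": "Drug resupply",
      "levels": [
        {"score": 1, "description": "automatic"},
        {"score": 3, "description": "manual"}
      ]
    },
    {
      "item_id": 12,
      "section": "drug_preparation",
      "label": "Blindness",
      "levels": [
        {"score": 1, "description": "no"},
        {"score": 2, "description": "double-blind"},
        {"score": 3, "description": "pharm-unblinded"}
      ]
    },
    {
      "item_id": 13,
      "section": "drug_preparation",
      "label": "Dose preparation",
      "levels": [
        {"score": 1, "description": "ready-to-use drug"},
        {"score": 2, "description": "personalized dose"},
        {"score": 3, "description": "reconstitution of the drug + personalized dose"}
      ]
    },
    {
      "item_id": 14,
      "section": "drug_preparation",
      "label": "Drug preparation procedure",
      "levels": [
        {"score": 0, "description": "all other cases"},
        {"score": 2, "description": "prohibition of use of closed system transfer devices"},
        {"score": 3, "description": "preparation time exceeding 20 min"}
      ]
    },
    {
      "item_id": 15,
      "section": "drug_preparation",
      "label": "Personalized administration",
      "levels": [
        {"score": 0, "description": "all other cases"},
        {"score": 3, "description": "personalized instruction (dose-preparation-based)"}
      ]
    }
  ]
}
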