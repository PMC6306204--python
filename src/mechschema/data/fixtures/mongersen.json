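{
  "format_version": "1.0",
  "schema": {
    "allow_feedback": true,
    "branch_logic": [
      {
        "direction": "join",
        "logic": "AND",
        "node_id": "mm_relief"
      },
      {
        "direction": "split",
        "logic": "AND",
        "node_id": "ssp_anti_inc"
      },
      {
        "direction": "join",
        "logic": "AND",
        "node_id": "ssp_smad7"
      }
    ],
    "disease": "Crohn disease",
    "edges": [
      [
        "mm_calm",
        "ssp_activity"
      ],
      [
        "mm_fb",
        "ssp_smad7"
      ],
      [
        "mm_relief",
        "ssp_anti_inc"
      ],
      [
        "ssp_anti_dec",
        "mm_relief"
      ],
      [
        "ssp_anti_inc",
        "mm_calm"
      ],
      [
        "ssp_anti_inc",
        "mm_fb"
      ],
      [
        "ssp_smad7",
        "mm_relief"
      ],
      [
        "trg1",
        "ssp_smad7"
      ]
    ],
    "id": "drug-mongersen",
    "interventions": [
      {
        "attached_to": "ssp_smad7",
        "id": "ivn1",
        "label": "Mongersen antisense oligonucleotide",
        "status": "existing"
      }
    ],
    "locus": "SMAD7",
    "metadata": {
      "curator": "mechschema fixtures",
      "version": "1"
    },
    "mms": [
      {
        "activity_description": "",
        "confidence": 3,
        "evidence": [],
        "id": "mm_calm",
        "known": true,
        "mm_class": "suppression of mucosal inflammation",
        "participating_entities": [],
        "telescoped_ref": null,
        "uncertain_existence": false
      },
      {
        "activity_description": "negative feedback loop closing on SMAD7",
        "confidence": 3,
        "evidence": [],
        "id": "mm_fb",
        "known": true,
        "mm_class": "TGFβ1 induction of SMAD7 expression",
        "participating_entities": [],
        "telescoped_ref": null,
        "uncertain_existence": false
      },
      {
        "activity_description": "with less SMAD7, TGFβ1 receptor signaling is no longer blocked",
        "confidence": 4,
        "evidence": [],
        "id": "mm_relief",
        "known": true,
        "mm_class": "decreased suppression of TGFβ1 signaling",
        "participating_entities": [],
        "telescoped_ref": null,
        "uncertain_existence": false
      }
    ],
    "ssps": [
      {
        "confidence": 4,
        "description": "",
        "entity": "Crohn disease activity",
        "entity_ref": null,
        "evidence": [],
        "id": "ssp_activity",
        "modifier": "decreased",
        "perturbation_class": "disease activity",
        "stage": "OrganismPhenotype"
      },
      {
        "confidence": 4,
        "description": "pre-existing disease perturbation: SMAD7 reduces the anti-inflammatory response to TGFβ1",
        "entity": "anti-inflammatory response to TGFβ1",
        "entity_ref": null,
        "evidence": [],
        "id": "ssp_anti_dec",
        "modifier": "decreased",
        "perturbation_class": "cell response",
        "stage": "Cell"
      },
      {
        "confidence": 3,
        "description": "",
        "entity": "anti-inflammatory response",
        "entity_ref": null,
        "evidence": [],
        "id": "ssp_anti_inc",
        "modifier": "increased",
        "perturbation_class": "tissue response",
        "stage": "Tissue"
      },
      {
        "confidence": 4,
        "description": "antisense knockdown lowers SMAD7 protein",
        "entity": "SMAD7",
        "entity_ref": null,
        "evidence": [],
        "id": "ssp_smad7",
        "modifier": "decreased",
        "perturbation_class": "protein abundance",
        "stage": "Protein"
      }
    ],
    "triggers": [
      {
        "detail": "antisense oligonucleotide inhibitor of SMAD7 expression",
        "id": "trg1",
        "kind": "drug_intervention",
        "label": "Mongersen"
      }
    ]
  }
}
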