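[
  {
    "study_id": "bard1_breast_cc_65057",
    "gene": "BARD1",
    "disease": "Breast Cancer",
    "effect_type": "OR",
    "point_estimate": 2.16,
    "ci_low": 1.31,
    "ci_high": 3.63,
    "p_value": null,
    "n_carriers": 117,
    "design": "CASE_CONTROL",
    "ascertainment_note": "large case-control series of 65,057 women with breast cancer; carrier prevalence 0.18%"
  },
  {
    "study_id": "atm_gastric_gwas",
    "gene": "ATM",
    "disease": "Gastric Cancer",
    "effect_type": "OR",
    "point_estimate": 4.74,
    "ci_low": null,
    "ci_high": null,
    "p_value": 8.0e-12,
    "n_carriers": null,
    "design": "GWAS",
    "ascertainment_note": "population-based GWAS, 2,500 gastric cancer cases and 205,652 controls; loss-of-function variants"
  },
  {
    "study_id": "chek2_gastric_cc",
    "gene": "CHEK2",
    "disease": "Gastric Cancer",
    "effect_type": "OR",
    "point_estimate": 1.6,
    "ci_low": null,
    "ci_high": null,
    "p_value": 0.004,
    "n_carriers": null,
    "design": "CASE_CONTROL",
    "ascertainment_note": "unselected gastric cancer cases; significant but below the two-fold threshold"
  },
  {
    "study_id": "chek2_gastric_cohort",
    "gene": "CHEK2",
    "disease": "Gastric Cancer",
    "effect_type": "HR",
    "point_estimate": 5.76,
    "ci_low": 2.12,
    "ci_high": 15.6,
    "p_value": null,
    "n_carriers": null,
    "design": "COHORT",
    "ascertainment_note": "general-population cohort of 86,975 individuals; 1100delC heterozygotes, age- and sex-adjusted"
  },
  {
    "study_id": "chek2_kidney_cohort",
    "gene": "CHEK2",
    "disease": "Kidney Cancer",
    "effect_type": "HR",
    "point_estimate": 3.61,
    "ci_low": 1.33,
    "ci_high": 9.79,
    "p_value": null,
    "n_carriers": null,
    "design": "COHORT",
    "ascertainment_note": "general-population cohort of 86,975 individuals; 1100delC heterozygotes, age- and sex-adjusted"
  },
  {
    "study_id": "chek2_thyroid_cc",
    "gene": "CHEK2",
    "disease": "Thyroid Cancer",
    "effect_type": "OR",
    "point_estimate": 3.3,
    "ci_low": null,
    "ci_high": null,
    "p_value": 0.0001,
    "n_carriers": null,
    "design": "CASE_CONTROL",
    "ascertainment_note": "15.6% carrier rate in unselected papillary thyroid cancer vs 6.0% in matched controls; printed as p < 0.0001"
  },
  {
    "study_id": "chek2_thyroid_variant",
    "gene": "CHEK2",
    "disease": "Thyroid Cancer",
    "effect_type": "OR",
    "point_estimate": 12.81,
    "ci_low": null,
    "ci_high": null,
    "p_value": 0.019,
    "n_carriers": null,
    "design": "CASE_CONTROL",
    "ascertainment_note": "c.470C allele, papillary thyroid carcinoma in female patients"
  },
  {
    "study_id": "chek2_male_breast_population",
    "gene": "CHEK2",
    "disease": "Male Breast Cancer",
    "effect_type": "OR",
    "point_estimate": 4.1,
    "ci_low": 1.2,
    "ci_high": 14.3,
    "p_value": 0.05,
    "n_carriers": null,
    "design": "CASE_CONTROL",
    "ascertainment_note": "1100delC in 4.2% of unselected male breast cancer cases vs 1.1% of 1,692 controls"
  },
  {
    "study_id": "chek2_male_breast_panel",
    "gene": "CHEK2",
    "disease": "Male Breast Cancer",
    "effect_type": "OR",
    "point_estimate": 3.7,
    "ci_low": null,
    "ci_high": null,
    "p_value": 6.24e-24,
    "n_carriers": null,
    "design": "CASE_CONTROL",
    "ascertainment_note": "715 male breast cancer patients with multi-gene panel testing"
  },
  {
    "study_id": "palb2_male_breast_families",
    "gene": "PALB2",
    "disease": "Male Breast Cancer",
    "effect_type": "RR",
    "point_estimate": 7.34,
    "ci_low": 1.28,
    "ci_high": 42.18,
    "p_value": 0.026,
    "n_carriers": null,
    "design": "FAMILY_BASED",
    "ascertainment_note": "524 families with pathogenic variants from 21 countries"
  },
  {
    "study_id": "palb2_male_breast_panel",
    "gene": "PALB2",
    "disease": "Male Breast Cancer",
    "effect_type": "OR",
    "point_estimate": 6.6,
    "ci_low": null,
    "ci_high": null,
    "p_value": 0.01,
    "n_carriers": null,
    "design": "CASE_CONTROL",
    "ascertainment_note": "715 male breast cancer patients with multi-gene panel testing"
  },
  {
    "study_id": "chek2_gastric_young_onset",
    "gene": "CHEK2",
    "disease": "Gastric Cancer",
    "effect_type": "OR",
    "point_estimate": 2.1,
    "ci_low": null,
    "ci_high": null,
    "p_value": 0.01,
    "n_carriers": null,
    "design": "CASE_CONTROL",
    "ascertainment_note": "young-onset gastric cancer subgroup"
  }
]
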