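# Default drug vocabulary, dose-threshold table and shipped criterion rule set.
#
# Coding-system duality: every class carries both ATC prefixes and dotted BNF
# section/chemical prefixes so the same rule set can be run against either
# dialect of dispensing data.
#
# Dose thresholds are formulary-derived PLACEHOLDERS (typical adult maintenance
# daily doses); override them for any real analysis.
#
# example_*_codes are the concrete full codes the bundled simulator dispenses;
# default_strength_mg / default_quantity are plausibility defaults (28-unit
# monthly packs), not sourced from any published marginal distribution.

systems: [ATC, BNF]

classes:
  - id: strong_opioids
    label: Strong opioids
    atc_prefixes: [N02AA, N02AB, N02AE]
    bnf_prefixes: ["4.7.2"]
    example_atc_codes: [N02AA01, N02AA05]
    example_bnf_codes: ["4.7.2.morphine", "4.7.2.oxycodone"]
    default_strength_mg: 10
  - id: osmotic_laxatives
    label: Osmotic laxatives
    atc_prefixes: [A06AD]
    bnf_prefixes: ["1.6.4"]
    example_atc_codes: [A06AD11, A06AD65]
    example_bnf_codes: ["1.6.4.lactulose", "1.6.4.macrogol"]
    default_strength_mg: 10
  - id: stimulant_laxatives
    label: Stimulant laxatives
    atc_prefixes: [A06AB]
    bnf_prefixes: ["1.6.2"]
    example_atc_codes: [A06AB02, A06AB06]
    example_bnf_codes: ["1.6.2.bisacodyl", "1.6.2.senna"]
    default_strength_mg: 5
  - id: ppi
    label: Proton pump inhibitors
    atc_prefixes: [A02BC]
    bnf_prefixes: ["1.3.5"]
    example_atc_codes: [A02BC01, A02BC02]
    example_bnf_codes: ["1.3.5.omeprazole", "1.3.5.pantoprazole"]
    default_strength_mg: 20
  - id: benzodiazepines
    label: Benzodiazepines
    atc_prefixes: [N05BA, N05CD]
    bnf_prefixes: ["4.1.2", "4.1.1.temazepam", "4.1.1.nitrazepam"]
    example_atc_codes: [N05BA01, N05BA04]
    example_bnf_codes: ["4.1.2.diazepam", "4.1.1.temazepam"]
    default_strength_mg: 5
  - id: z_drugs
    label: Non-benzodiazepine hypnotics (Z-drugs)
    atc_prefixes: [N05CF]
    bnf_prefixes: ["4.1.1.zopiclone", "4.1.1.zolpidem"]
    example_atc_codes: [N05CF01, N05CF02]
    example_bnf_codes: ["4.1.1.zopiclone", "4.1.1.zolpidem"]
    default_strength_mg: 7.5
  - id: first_gen_antihistamines
    label: First-generation antihistamines
    atc_prefixes: [R06AB, R06AD, R06AA02]
    bnf_prefixes: ["3.4.1.chlorphenamine", "3.4.1.promethazine"]
    example_atc_codes: [R06AB04, R06AD02]
    example_bnf_codes: ["3.4.1.chlorphenamine", "3.4.1.promethazine"]
    default_strength_mg: 4
  - id: second_gen_antihistamines
    label: Second-generation antihistamines
    atc_prefixes: [R06AE07, R06AX13, R06AX26]
    bnf_prefixes: ["3.4.1.cetirizine", "3.4.1.loratadine"]
    example_atc_codes: [R06AE07, R06AX13]
    example_bnf_codes: ["3.4.1.cetirizine", "3.4.1.loratadine"]
    default_strength_mg: 10
  - id: nsaids
    label: Non-steroidal anti-inflammatory drugs
    atc_prefixes: [M01AB, M01AC, M01AE, M01AH]
    bnf_prefixes: ["10.1.1"]
    example_atc_codes: [M01AE01, M01AB05]
    example_bnf_codes: ["10.1.1.ibuprofen", "10.1.1.diclofenac"]
    default_strength_mg: 200
  - id: tca
    label: Tricyclic antidepressants
    atc_prefixes: [N06AA]
    bnf_prefixes: ["4.3.1"]
    example_atc_codes: [N06AA09, N06AA10]
    example_bnf_codes: ["4.3.1.amitriptyline", "4.3.1.nortriptyline"]
    default_strength_mg: 25
  - id: ssri
    label: Selective serotonin reuptake inhibitors
    atc_prefixes: [N06AB]
    bnf_prefixes: ["4.3.3"]
    example_atc_codes: [N06AB06, N06AB03]
    example_bnf_codes: ["4.3.3.sertraline", "4.3.3.fluoxetine"]
    default_strength_mg: 50
  # Filler classes: background / polypharmacy load not referenced by any rule.
  - id: statins
    label: Lipid-regulating drugs
    atc_prefixes: [C10AA]
    bnf_prefixes: ["2.12"]
    example_atc_codes: [C10AA01, C10AA05]
    example_bnf_codes: ["2.12.simvastatin", "2.12.atorvastatin"]
    default_strength_mg: 20
  - id: ace_inhibitors
    label: ACE inhibitors
    atc_prefixes: [C09AA]
    bnf_prefixes: ["2.5.5"]
    example_atc_codes: [C09AA05]
    example_bnf_codes: ["2.5.5.ramipril"]
    default_strength_mg: 5
  - id: beta_blockers
    label: Beta-adrenoceptor blockers
    atc_prefixes: [C07AB]
    bnf_prefixes: ["2.4"]
    example_atc_codes: [C07AB02]
    example_bnf_codes: ["2.4.atenolol"]
    default_strength_mg: 50
  - id: biguanides
    label: Biguanide antidiabetics
    atc_prefixes: [A10BA]
    bnf_prefixes: ["6.1.2"]
    example_atc_codes: [A10BA02]
    example_bnf_codes: ["6.1.2.metformin"]
    default_strength_mg: 500
  - id: thyroid_hormones
    label: Thyroid hormones
    atc_prefixes: [H03AA]
    bnf_prefixes: ["6.2.1"]
    example_atc_codes: [H03AA01]
    example_bnf_codes: ["6.2.1.levothyroxine"]
    default_strength_mg: 0.1

dose_thresholds:
  # maintenance_mg_per_day: typical adult maintenance daily dose (placeholder).
  - {system: ATC, prefix: A02BC01, maintenance_mg_per_day: 20}   # omeprazole
  - {system: ATC, prefix: A02BC02, maintenance_mg_per_day: 40}   # pantoprazole
  - {system: ATC, prefix: A02BC03, maintenance_mg_per_day: 15}   # lansoprazole
  - {system: ATC, prefix: A02BC04, maintenance_mg_per_day: 20}   # rabeprazole
  - {system: ATC, prefix: A02BC05, maintenance_mg_per_day: 20}   # esomeprazole
  - {system: BNF, prefix: "1.3.5.omeprazole", maintenance_mg_per_day: 20}
  - {system: BNF, prefix: "1.3.5.pantoprazole", maintenance_mg_per_day: 40}
  - {system: BNF, prefix: "1.3.5.lansoprazole", maintenance_mg_per_day: 15}
  - {system: BNF, prefix: "1.3.5.esomeprazole", maintenance_mg_per_day: 20}

criteria:
  - id: benzo_gt_4w
    label: Benzodiazepines used for more than 4 weeks
    category: DURATION
    target_class: benzodiazepines
    max_duration_days: 28
  - id: z_drug_gt_4w
    label: Non-benzodiazepine hypnotics used for more than 4 weeks
    category: DURATION
    target_class: z_drugs
    max_duration_days: 28
  - id: nsaid_gt_3m
    label: NSAIDs used for more than 3 months
    category: DURATION
    target_class: nsaids
    max_duration_days: 90
  - id: ppi_high_dose_gt8w
    label: PPIs above maintenance dosage for more than 8 weeks
    category: DOSE_DURATION
    target_class: ppi
    max_duration_days: 56
  - id: opioid_no_laxative
    label: Strong opioids without co-prescribed osmotic or stimulant laxative
    category: CO_PRESCRIPTION
    target_class: strong_opioids
    required_classes: [osmotic_laxatives, stimulant_laxatives]
    window: same_month
  - id: first_gen_antihistamine_first_line_gt7d
    label: First-generation antihistamines first-line for more than 7 days
    category: FIRST_LINE
    target_class: first_gen_antihistamines
    max_duration_days: 7
    preferred_alternative_classes: [second_gen_antihistamines]
  - id: tca_first_line
    label: TCAs used first-line in depression
    category: FIRST_LINE
    target_class: tca
    preferred_alternative_classes: [ssri]
  - id: duplicate_opioids
    label: Duplicate strong opioids within one month
    category: DUPLICATION
    target_class: strong_opioids
  - id: duplicate_benzodiazepines
    label: Duplicate benzodiazepines within one month
    category: DUPLICATION
    target_class: benzodiazepines
  - id: duplicate_nsaids
    label: Duplicate NSAIDs within one month
    category: DUPLICATION
    target_class: nsaids
  - id: duplicate_stimulant_laxatives
    label: Duplicate stimulant laxatives within one month
    category: DUPLICATION
    target_class: stimulant_laxatives

settings:
  gap_tolerance_days: 63
  default_coverage_days: 28
  polypharmacy_min_dispensings: 3
  polypharmacy_min_classes: 4
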