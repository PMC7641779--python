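# Default pharmacogenomics knowledge-model registry.
#
# Semantic types carry their attribute inventories; `auxiliary: true` marks
# extension types that are not part of the six core types (Mutation exists so
# that gene-mutation assertions can be expressed as triples rather than only
# as a Gene attribute).
#
# Relations: tree numbers are dotted codes; a code with no dot is first-level,
# one dot is second-level. Relations flagged `reconstructed: true` complete
# the 26-relation inventory from the melanoma relationship groups and carry
# placeholder definitions — curators are expected to re-key them.
version: 1
semantic_types:
  - name: Drug
    attributes: [DrugName, Description, ChemicalFormula, MolecularWeight,
                 DrugApprovalStatus, CAS, UNII, PharmacologyIndication]
  - name: Gene
    attributes: [GeneName, Mutation]
  - name: Disease
    attributes: [DiseaseName, Position]
  - name: AdverseReaction
    attributes: []
  - name: Population
    attributes: [PediatricUsePopulation, ApplicablePopulation, Gender, Age, Race]
  - name: DrugUse
    attributes: [DailyDose, DoseForm, Frequency, TakeTimeFor, TakeWithMeal]
  - name: Mutation
    auxiliary: true
    attributes: [MutationName]
relations:
  - rid: R01
    relationship: treats
    domain: Drug
    range: Disease
    tree_number: R01
    definition: The drug is indicated for the treatment of the disease.
  - rid: R02
    relationship: synergized_by
    domain: Drug
    range: Drug
    tree_number: R02
    definition: The drug is used in combination with another drug.
  - rid: R03
    relationship: antagonized_by
    domain: Drug
    range: Drug
    tree_number: R03
    definition: Concurrent administration of the two drugs should be avoided.
  - rid: R04
    relationship: have_dosage
    domain: Drug
    range: DrugUse
    tree_number: R04
    definition: The drug has the stated dosage instruction.
  - rid: R05
    relationship: have_mutation
    domain: Gene
    range: Mutation
    tree_number: R05
    definition: The gene carries the stated mutation.
  - rid: R06
    relationship: is_biomarker_efficacy_of
    domain: Gene
    range: Drug
    tree_number: R06
    definition: The gene variant is a biomarker for the efficacy of the drug.
  - rid: R07
    relationship: is_biomarker_prognosis_of
    domain: Gene
    range: Disease
    tree_number: R07
    definition: The gene variant is a prognostic biomarker for the disease.
  - rid: R08
    relationship: has_dose_form
    domain: Drug
    range: DrugUse
    tree_number: R08
    definition: The drug is distributed in the stated dose form.
    inverse_of: R09
  - rid: R09
    relationship: dose_form_of
    domain: DrugUse
    range: Drug
    tree_number: R09
    definition: The dose form belongs to the drug.
    inverse_of: R08
  - rid: R10
    relationship: causes
    domain: Gene
    range: Disease
    tree_number: R10
    definition: Placeholder — gene mutation causes the disease.
    reconstructed: true
  - rid: R11
    relationship: targets
    domain: Drug
    range: Gene
    tree_number: R11
    definition: Placeholder — the drug targets the gene product.
    reconstructed: true
  - rid: R12
    relationship: has_adverse_reaction
    domain: Drug
    range: AdverseReaction
    tree_number: R12
    definition: Placeholder — the drug is associated with the adverse reaction.
    reconstructed: true
  - rid: R13
    relationship: used_in_population
    domain: Drug
    range: Population
    tree_number: R13
    definition: Placeholder — use of the drug in a specific population.
    reconstructed: true
  - rid: R14
    relationship: adjusts_dosage
    domain: AdverseReaction
    range: DrugUse
    tree_number: R14
    definition: Placeholder — the adverse reaction selects an adjusted dosage instruction.
    reconstructed: true
  - rid: R01.01
    relationship: prevents
    domain: Drug
    range: Disease
    tree_number: R01.01
    definition: Placeholder — the drug is indicated for the prevention of the disease.
    reconstructed: true
  - rid: R01.02
    relationship: relieves_symptoms_of
    domain: Drug
    range: Disease
    tree_number: R01.02
    definition: Placeholder — the drug relieves the signs and symptoms of the disease.
    reconstructed: true
  - rid: R01.03
    relationship: monotherapy_for
    domain: Drug
    range: Disease
    tree_number: R01.03
    definition: Placeholder — the drug is indicated as monotherapy for the disease.
    reconstructed: true
  - rid: R02.01
    relationship: coadministered_with
    domain: Drug
    range: Drug
    tree_number: R02.01
    definition: Placeholder — the drugs are coadministered.
    reconstructed: true
  - rid: R03.01
    relationship: avoid_concurrent_use_with
    domain: Drug
    range: Drug
    tree_number: R03.01
    definition: Placeholder — concurrent use of the drugs should be avoided.
    reconstructed: true
  - rid: R04.01
    relationship: has_routine_dosage
    domain: Drug
    range: DrugUse
    tree_number: R04.01
    definition: Placeholder — the routine (label-recommended) dosage of the drug.
    reconstructed: true
  - rid: R04.02
    relationship: has_adjusted_dosage
    domain: Drug
    range: DrugUse
    tree_number: R04.02
    definition: Placeholder — a context-adjusted dosage instruction of the drug.
    reconstructed: true
  - rid: R04.03
    relationship: has_frequency
    domain: Drug
    range: DrugUse
    tree_number: R04.03
    definition: Placeholder — the administration frequency of the drug.
    reconstructed: true
  - rid: R12.01
    relationship: may_cause
    domain: Drug
    range: AdverseReaction
    tree_number: R12.01
    definition: Placeholder — the drug may cause the adverse reaction.
    reconstructed: true
  - rid: R13.01
    relationship: pediatric_use_in
    domain: Drug
    range: Population
    tree_number: R13.01
    definition: Placeholder — pediatric use of the drug in the population.
    reconstructed: true
  - rid: R14.01
    relationship: requires_discontinuation_on
    domain: AdverseReaction
    range: DrugUse
    tree_number: R14.01
    definition: Placeholder — the adverse reaction requires permanent discontinuation.
    reconstructed: true
  - rid: R14.02
    relationship: population_adjusts_dosage
    domain: Population
    range: DrugUse
    tree_number: R14.02
    definition: Placeholder — the population selects an adjusted dosage instruction.
    reconstructed: true
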