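# Packaged intracellular signaling model of one endothelial cell.
#
# 21 species (14 integrated per cell, 7 boundary/environment) and 43
# parameters covering Dll4-Notch1 lateral inhibition with cis-inhibition and
# notch1 auto-activation, NICD-controlled transcription of the VEGF
# receptors, and VEGF-A binding kinetics of mVEGFR1, sVEGFR1 and VEGFR2.
# Amounts are particle numbers per cell; rates are per hour.
schema: angiosprout-model/1
name: ec_intracellular
species:
  # --- integrated per cell ---
  - {id: notch1_mRNA, initial: 80.0}
  - {id: notch1, initial: 800.0}
  - {id: dll4_mRNA, initial: 5.0}
  - {id: dll4, initial: 10.0}
  - {id: nicd, initial: 400.0}
  - {id: cis_complex, initial: 0.0}
  - {id: vegfr1_mRNA, initial: 150.0}
  - {id: mvegfr1, initial: 300.0}
  - {id: svegfr1_internal, initial: 100.0}
  - {id: mvegfr1_bound, initial: 0.0}
  - {id: vegfr2_mRNA, initial: 10.0}
  - {id: vegfr2, initial: 50.0}
  - {id: vegfr2_bound, initial: 0.0}
  - {id: vegfr2_active, initial: 0.0}
  # --- boundary / environment ---
  - {id: vegf_ext, initial: 396.0, boundary: true}
  - {id: dll4_nb, initial: 0.0, boundary: true}
  - {id: svegfr1_ext, initial: 0.0, boundary: true}
  - {id: svegfr1b_ext, initial: 0.0, boundary: true}
  - {id: vegf_medium, initial: 44.0, boundary: true}
  - {id: source, initial: 0.0, boundary: true}
  - {id: sink, initial: 0.0, boundary: true}
parameters:
  # Hill exponent shared by all transcription laws
  h: 2.0
  # transcription (Hill laws)
  vmax_tc_notch1: 25.0
  a_nicd_notch1: 4.0
  m0_nicd_notch1: 100.0
  a_auto_notch1: 2.0
  m0_auto_notch1: 400.0
  vmax_tc_vegfr1: 56.0
  a_nicd_vegfr1: 10.0
  m0_nicd_vegfr1: 250.0
  vmax_tc_vegfr2: 20.0
  a_nicd_vegfr2: 30.0
  m0_nicd_vegfr2: 70.0
  vmax_tc_dll4: 40.0
  a_v2_dll4: 10.0
  m0_v2_dll4: 250.0
  # translation
  k_tl_notch1: 4.0
  k_tl_dll4: 2.75
  k_tl_mvegfr1: 0.5
  k_tl_svegfr1: 1.0
  k_tl_vegfr2: 1.0
  # mRNA degradation
  k_deg_notch1_mrna: 0.2
  k_deg_dll4_mrna: 0.4
  k_deg_vegfr1_mrna: 0.2
  k_deg_vegfr2_mrna: 0.2
  # protein / complex degradation
  k_deg_notch1: 0.2
  k_deg_dll4: 0.5
  k_nicd_degradation: 0.5
  k_deg_mvegfr1: 0.2
  k_deg_svegfr1: 0.5
  k_deg_vegfr2: 0.2
  k_deg_cis: 0.5
  k_deg_mvegfr1_bound: 0.5
  k_deg_vegfr2_bound: 0.1
  # Dll4-Notch1 binding
  kc: 0.001
  kt: 0.01
  # VEGF association / dissociation
  kon_mvegfr1: 4.0e-3
  koff_mvegfr1: 0.1
  kon_svegfr1: 4.0e-3
  koff_svegfr1: 0.1
  kon_vegfr2: 2.0e-3
  koff_vegfr2: 1.0
  # VEGFR2a relaxation back to the free receptor pool
  k_act_decay: 1.0
  # sVEGFR1 export
  k_export: 1.0
reactions:
  # --- transcription ---
  - id: tc_notch1
    kind: hill_activation
    product: notch1_mRNA
    vmax: vmax_tc_notch1
    h: h
    terms:
      - {modifier: [nicd], a: a_nicd_notch1, m0: m0_nicd_notch1}
      - {modifier: [notch1], a: a_auto_notch1, m0: m0_auto_notch1}
  - id: tc_vegfr1
    kind: hill_activation
    product: vegfr1_mRNA
    vmax: vmax_tc_vegfr1
    h: h
    terms:
      - {modifier: [nicd], a: a_nicd_vegfr1, m0: m0_nicd_vegfr1}
  - id: tc_vegfr2
    kind: hill_repression
    product: vegfr2_mRNA
    vmax: vmax_tc_vegfr2
    h: h
    terms:
      - {modifier: [nicd], a: a_nicd_vegfr2, m0: m0_nicd_vegfr2}
  - id: tc_dll4
    kind: hill_activation
    product: dll4_mRNA
    vmax: vmax_tc_dll4
    h: h
    terms:
      - {modifier: [vegfr2_bound, vegfr2_active], a: a_v2_dll4, m0: m0_v2_dll4}
  # --- translation (mRNA is a template, not consumed) ---
  - {id: tl_notch1, kind: mass_action, k: k_tl_notch1, rate_species: [notch1_mRNA], consume: [], produce: [notch1]}
  - {id: tl_dll4, kind: mass_action, k: k_tl_dll4, rate_species: [dll4_mRNA], consume: [], produce: [dll4]}
  - {id: tl_mvegfr1, kind: mass_action, k: k_tl_mvegfr1, rate_species: [vegfr1_mRNA], consume: [], produce: [mvegfr1]}
  - {id: tl_svegfr1, kind: mass_action, k: k_tl_svegfr1, rate_species: [vegfr1_mRNA], consume: [], produce: [svegfr1_internal]}
  - {id: tl_vegfr2, kind: mass_action, k: k_tl_vegfr2, rate_species: [vegfr2_mRNA], consume: [], produce: [vegfr2]}
  # --- mRNA degradation ---
  - {id: deg_notch1_mrna, kind: mass_action, k: k_deg_notch1_mrna, rate_species: [notch1_mRNA], consume: [notch1_mRNA], produce: [sink]}
  - {id: deg_dll4_mrna, kind: mass_action, k: k_deg_dll4_mrna, rate_species: [dll4_mRNA], consume: [dll4_mRNA], produce: [sink]}
  - {id: deg_vegfr1_mrna, kind: mass_action, k: k_deg_vegfr1_mrna, rate_species: [vegfr1_mRNA], consume: [vegfr1_mRNA], produce: [sink]}
  - {id: deg_vegfr2_mrna, kind: mass_action, k: k_deg_vegfr2_mrna, rate_species: [vegfr2_mRNA], consume: [vegfr2_mRNA], produce: [sink]}
  # --- protein / complex degradation ---
  - {id: deg_notch1, kind: mass_action, k: k_deg_notch1, rate_species: [notch1], consume: [notch1], produce: [sink]}
  - {id: deg_dll4, kind: mass_action, k: k_deg_dll4, rate_species: [dll4], consume: [dll4], produce: [sink]}
  - {id: deg_nicd, kind: mass_action, k: k_nicd_degradation, rate_species: [nicd], consume: [nicd], produce: [sink]}
  - {id: deg_mvegfr1, kind: mass_action, k: k_deg_mvegfr1, rate_species: [mvegfr1], consume: [mvegfr1], produce: [sink]}
  - {id: deg_svegfr1, kind: mass_action, k: k_deg_svegfr1, rate_species: [svegfr1_internal], consume: [svegfr1_internal], produce: [sink]}
  - {id: deg_vegfr2, kind: mass_action, k: k_deg_vegfr2, rate_species: [vegfr2], consume: [vegfr2], produce: [sink]}
  - {id: deg_cis, kind: mass_action, k: k_deg_cis, rate_species: [cis_complex], consume: [cis_complex], produce: [sink]}
  - {id: deg_mvegfr1_bound, kind: mass_action, k: k_deg_mvegfr1_bound, rate_species: [mvegfr1_bound], consume: [mvegfr1_bound], produce: [sink]}
  - {id: deg_vegfr2_bound, kind: mass_action, k: k_deg_vegfr2_bound, rate_species: [vegfr2_bound], consume: [vegfr2_bound], produce: [sink]}
  # --- Dll4-Notch1 binding ---
  - {id: cis_binding, kind: mass_action, k: kc, rate_species: [notch1, dll4], consume: [notch1, dll4], produce: [cis_complex]}
  - {id: trans_binding, kind: mass_action, k: kt, rate_species: [notch1, dll4_nb], consume: [notch1, dll4_nb], produce: [nicd]}
  # --- VEGF binding kinetics of the cell-surface receptors ---
  - {id: mvegfr1_assoc, kind: mass_action, k: kon_mvegfr1, rate_species: [mvegfr1, vegf_ext], consume: [mvegfr1, vegf_ext], produce: [mvegfr1_bound]}
  - {id: mvegfr1_dissoc, kind: mass_action, k: koff_mvegfr1, rate_species: [mvegfr1_bound], consume: [mvegfr1_bound], produce: [mvegfr1, vegf_ext]}
  - {id: vegfr2_assoc, kind: mass_action, k: kon_vegfr2, rate_species: [vegfr2, vegf_ext], consume: [vegfr2, vegf_ext], produce: [vegfr2_bound]}
  - {id: vegfr2_dissoc, kind: mass_action, k: koff_vegfr2, rate_species: [vegfr2_bound], consume: [vegfr2_bound], produce: [vegfr2_active, vegf_ext]}
  - {id: vegfr2a_decay, kind: mass_action, k: k_act_decay, rate_species: [vegfr2_active], consume: [vegfr2_active], produce: [vegfr2]}
  # --- sVEGFR1 export ---
  - {id: svegfr1_export, kind: mass_action, k: k_export, rate_species: [svegfr1_internal], consume: [svegfr1_internal], produce: [svegfr1_ext]}
  # --- extracellular sVEGFR1/VEGF kinetics (handled by the field layer) ---
  - {id: svegfr1_assoc, kind: mass_action, k: kon_svegfr1, rate_species: [svegfr1_ext, vegf_ext], consume: [svegfr1_ext, vegf_ext], produce: [svegfr1b_ext]}
  - {id: svegfr1_dissoc, kind: mass_action, k: koff_svegfr1, rate_species: [svegfr1b_ext], consume: [svegfr1b_ext], produce: [svegfr1_ext, vegf_ext]}
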