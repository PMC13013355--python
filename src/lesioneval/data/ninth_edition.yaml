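# TNM 9th-edition rules for NSCLC: T size cuts, invasion upgrades,
# nodal-station map (with the N2a/N2b single/multi-station split),
# M site classes and the full (T,N,M) -> UICC stage-group lookup.
# This file is the single source of truth for staging; edit or swap
# it to use a different edition.
version: ninth_edition-1.0
stage_order:
- Occult
- IA1
- IA2
- IA3
- IB
- IIA
- IIB
- IIIA
- IIIB
- IIIC
- IVA
- IVB
t_order:
- Tx
- T1a
- T1b
- T1c
- T2a
- T2b
- T3
- T4
n_order:
- N0
- N1
- N2a
- N2b
- N3
m_order:
- M0
- M1a
- M1b
- M1c
t_size_thresholds_mm:
- max_mm: 10
  category: T1a
- max_mm: 20
  category: T1b
- max_mm: 30
  category: T1c
- max_mm: 40
  category: T2a
- max_mm: 50
  category: T2b
- max_mm: 70
  category: T3
- max_mm: null
  category: T4
invasion_map:
  chest_wall: T3
  parietal_pleura: T3
  phrenic_nerve: T3
  parietal_pericardium: T3
  mediastinum: T4
  diaphragm: T4
  heart: T4
  great_vessels: T4
  trachea: T4
  carina: T4
  oesophagus: T4
  recurrent_laryngeal_nerve: T4
  vertebral_body: T4
n_station_map:
  ipsilateral_peribronchial: N1
  ipsilateral_hilar: N1
  ipsilateral_intrapulmonary: N1
  ipsilateral_upper_paratracheal_2: N2
  ipsilateral_lower_paratracheal_4: N2
  aortopulmonary_window_5: N2
  para_aortic_6: N2
  subcarinal_7: N2
  ipsilateral_paraesophageal_8: N2
  ipsilateral_pulmonary_ligament_9: N2
  contralateral_mediastinal: N3
  contralateral_hilar: N3
  ipsilateral_supraclavicular: N3
  contralateral_supraclavicular: N3
  scalene: N3
m_intrathoracic_sites:
- contralateral_pulmonary
- contralateral_lung
- pleura
- pleural_effusion
- pericardial_effusion
- pericardial_nodule
m_extrathoracic_sites:
- liver
- brain
- adrenal_gland
- bone
- distant_lymph_node
- kidney
- peritoneal
- skin
- spleen
- soft_tissue
uicc_lookup:
  Tx:
    N0:
      M0: Occult
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N1:
      M0: IIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2a:
      M0: IIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2b:
      M0: IIIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N3:
      M0: IIIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
  T1a:
    N0:
      M0: IA1
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N1:
      M0: IIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2a:
      M0: IIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2b:
      M0: IIIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N3:
      M0: IIIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
  T1b:
    N0:
      M0: IA2
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N1:
      M0: IIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2a:
      M0: IIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2b:
      M0: IIIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N3:
      M0: IIIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
  T1c:
    N0:
      M0: IA3
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N1:
      M0: IIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2a:
      M0: IIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2b:
      M0: IIIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N3:
      M0: IIIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
  T2a:
    N0:
      M0: IB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N1:
      M0: IIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2a:
      M0: IIIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2b:
      M0: IIIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N3:
      M0: IIIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
  T2b:
    N0:
      M0: IIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N1:
      M0: IIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2a:
      M0: IIIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2b:
      M0: IIIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N3:
      M0: IIIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
  T3:
    N0:
      M0: IIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N1:
      M0: IIIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2a:
      M0: IIIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2b:
      M0: IIIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N3:
      M0: IIIC
      M1a: IVA
      M1b: IVA
      M1c: IVB
  T4:
    N0:
      M0: IIIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N1:
      M0: IIIA
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2a:
      M0: IIIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N2b:
      M0: IIIB
      M1a: IVA
      M1b: IVA
      M1c: IVB
    N3:
      M0: IIIC
      M1a: IVA
      M1b: IVA
      M1c: IVB
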