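{
 "WT": {},
 "shd": {
  "removals": [
   "iridophore"
  ],
  "m_density": 0.02,
  "note": "ltk mutant: no S-iridophores; fewer initial melanophores"
 },
 "nac": {
  "removals": [
   "melanophore"
  ],
  "note": "mitfa mutant: no melanophores"
 },
 "pfe": {
  "removals": [
   "xanthophore"
  ],
  "note": "csf1ra mutant: no xanthophore lineage"
 },
 "rse": {
  "init_id_fraction": 0.2,
  "note": "ednrb1a mutant: initial dense S-iridophores reduced to one fifth"
 },
 "sbr": {
  "param_overrides": {
   "trans_d2l_rate": 0.025
  },
  "note": "tjp1a mutant: dense-to-loose attempts 40x slower than loose-to-dense"
 },
 "cho": {
  "init_id_fraction": 0.0,
  "fixed_events": [
   {
    "label": "cho-seed-loose",
    "stage": "PR",
    "action": "seed_loose_iridophores",
    "count": 200
   }
  ],
  "note": "no horizontal myoseptum: no initial band; 200 loose S-iridophores appear at PR"
 },
 "seurat": {
  "param_scales": {
   "diff_m_per_id": 0.05,
   "diff_m_per_x": 0.05,
   "diff_m_solo": 0.05
  },
  "param_overrides": {
   "death_m_rate": 100.0
  },
  "note": "igsf11 mutant: melanophore differentiation 1/20, death attempts 100/day"
 },
 "leo-H1": {
  "param_overrides": {
   "s_m_from_x": 0.0
  },
  "note": "melanophores are not repelled by xanthophores"
 },
 "leo-H2": {
  "toggles": {
   "h2": true
  },
  "note": "xanthophores do not promote melanophore survival in the long range"
 },
 "leo-H3": {
  "toggles": {
   "d2l_no_xlong": true
  },
  "note": "xanthophores do not promote dense-to-loose transitions in the long range"
 },
 "leo-H4": {
  "toggles": {
   "h4": true
  },
  "note": "melanophores lose the local dense S-iridophore death/differentiation veto"
 },
 "leo-H5": {
  "zero_weights": [
   "diff_m_irid",
   "diff_m_loose"
  ],
  "note": "melanophore differentiation loses S-iridophore direction"
 },
 "leo": {
  "compose": [
   "leo-H1",
   "leo-H2",
   "leo-H3",
   "leo-H4",
   "leo-H5"
  ],
  "note": "cx39.4 mutant: hypotheses 1-5 combined"
 },
 "no-l2d": {
  "param_overrides": {
   "trans_l2d_rate": 0.0
  },
  "note": "knockout: loose-to-dense transitions disabled"
 },
 "no-d2l": {
  "param_overrides": {
   "trans_d2l_rate": 0.0
  },
  "note": "knockout: dense-to-loose transitions disabled"
 },
 "d2l-no-xshort": {
  "toggles": {
   "d2l_no_xshort": true
  },
  "note": "knockout: short-range xanthophore inhibition removed from dense-to-loose"
 },
 "l2d-no-mshort": {
  "toggles": {
   "l2d_no_mshort": true
  },
  "note": "knockout: short-range melanophore inhibition removed from loose-to-dense"
 },
 "l2d-no-xshort": {
  "toggles": {
   "l2d_no_xshort": true
  },
  "note": "knockout: short-range xanthophore promotion removed from loose-to-dense"
 },
 "no-movement": {
  "param_overrides": {
   "speed_m": 0.0,
   "speed_x": 0.0
  },
  "note": "knockout: melanophore and xanthophore movement disabled"
 },
 "no-xb-pull": {
  "param_overrides": {
   "s_m_to_xb": 0.0
  },
  "note": "knockout: long-range xanthoblast pull on melanophores removed"
 },
 "no-x-prolif": {
  "param_overrides": {
   "prolif_x": 0.0,
   "prolif_xb": 0.0
  },
  "note": "knockout: xanthophore/xanthoblast proliferation disabled"
 },
 "no-m-death": {
  "param_overrides": {
   "death_m_rate": 0.0
  },
  "note": "knockout: melanophore death disabled"
 },
 "diff-no-irid": {
  "param_overrides": {
   "diff_m_per_id": 0.0
  },
  "zero_weights": [
   "diff_m_irid",
   "diff_m_loose"
  ],
  "note": "knockout: melanophore differentiation independent of S-iridophores"
 },
 "diff-no-xan": {
  "param_overrides": {
   "diff_m_per_x": 0.0
  },
  "zero_weights": [
   "diff_m_xan"
  ],
  "note": "knockout: melanophore differentiation independent of xanthophores"
 },
 "no-chase-run": {
  "param_overrides": {
   "s_m_from_x": 0.0,
   "s_x_to_m": 0.0
  },
  "note": "knockout: mutual movement bias between melanophores and xanthophores removed"
 },
 "vertical-interstripe": {
  "initializer": "vertical_interstripe",
  "note": "experiment: initial dense band oriented dorso-ventrally"
 },
 "off-center-interstripe": {
  "initializer": "off_center_interstripe",
  "note": "experiment: initial dense band one quarter of the way up the domain"
 },
 "tall-domain": {
  "initializer": "tall_domain",
  "note": "experiment: initial domain 2 mm x 3 mm"
 },
 "pre-striped": {
  "initializer": "pre_striped",
  "note": "experiment: domain initialised with adult-width stripes and interstripes"
 }
}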