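# Rat whole-body physiology for a perfusion-limited PBPK model.
# Volumes and regional blood flows from standard physiological reference
# compilations; tissue composition (water / neutral lipid / neutral
# phospholipid / acidic phospholipid fractions) from the tissue-composition
# tables used for mechanistic partition-coefficient prediction.
# Flows are mL/min/kg body weight; volumes are L/kg body weight.
# The liver receives its arterial flow plus the portal outflow of gut,
# spleen and stomach; total hepatic blood flow is 6.2+40+5+4 = 55.2.
species: rat
body_weight_kg: 0.25
hematocrit: 0.46
cardiac_output_ml_min_kg: 296.0
gfr_ml_min_kg: 5.2
ph:
  plasma: 7.4
  intracellular: 7.0
  erythrocyte: 7.22
blood:
  arterial_volume_l_kg: 0.0245
  venous_volume_l_kg: 0.0495
erythrocyte_composition: {f_iw: 0.603, f_nl: 0.0017, f_np: 0.0029, ap_mg_g: 0.5}
organs:
  lung:    {volume_l_kg: 0.0050, flow_ml_min_kg: 296.0,
            composition: {f_ew: 0.336, f_iw: 0.446, f_nl: 0.0220, f_np: 0.0128, ap_mg_g: 3.91}}
  adipose: {volume_l_kg: 0.0760, flow_ml_min_kg: 20.7,
            composition: {f_ew: 0.135, f_iw: 0.017, f_nl: 0.8530, f_np: 0.0016, ap_mg_g: 0.40}}
  bone:    {volume_l_kg: 0.0730, flow_ml_min_kg: 36.1,
            composition: {f_ew: 0.100, f_iw: 0.346, f_nl: 0.0170, f_np: 0.0017, ap_mg_g: 0.67}}
  brain:   {volume_l_kg: 0.0057, flow_ml_min_kg: 5.9,
            composition: {f_ew: 0.162, f_iw: 0.620, f_nl: 0.0390, f_np: 0.0015, ap_mg_g: 0.40}}
  heart:   {volume_l_kg: 0.0033, flow_ml_min_kg: 14.5,
            composition: {f_ew: 0.320, f_iw: 0.456, f_nl: 0.0140, f_np: 0.0111, ap_mg_g: 2.25}}
  kidney:  {volume_l_kg: 0.0073, flow_ml_min_kg: 41.7,
            composition: {f_ew: 0.273, f_iw: 0.483, f_nl: 0.0120, f_np: 0.0242, ap_mg_g: 5.03}}
  muscle:  {volume_l_kg: 0.4040, flow_ml_min_kg: 82.3,
            composition: {f_ew: 0.118, f_iw: 0.630, f_nl: 0.0100, f_np: 0.0072, ap_mg_g: 1.53}}
  skin:    {volume_l_kg: 0.1900, flow_ml_min_kg: 17.2,
            composition: {f_ew: 0.382, f_iw: 0.291, f_nl: 0.0600, f_np: 0.0044, ap_mg_g: 1.32}}
  gut:     {volume_l_kg: 0.0270, flow_ml_min_kg: 40.0,
            composition: {f_ew: 0.282, f_iw: 0.475, f_nl: 0.0380, f_np: 0.0125, ap_mg_g: 2.41}}
  spleen:  {volume_l_kg: 0.0020, flow_ml_min_kg: 5.0,
            composition: {f_ew: 0.207, f_iw: 0.579, f_nl: 0.0077, f_np: 0.0113, ap_mg_g: 3.18}}
  stomach: {volume_l_kg: 0.0046, flow_ml_min_kg: 4.0,
            composition: {f_ew: 0.282, f_iw: 0.475, f_nl: 0.0380, f_np: 0.0125, ap_mg_g: 2.41}}
  gonads:  {volume_l_kg: 0.0025, flow_ml_min_kg: 1.4,
            composition: {f_ew: 0.150, f_iw: 0.626, f_nl: 0.0170, f_np: 0.0092, ap_mg_g: 2.30}}
  liver:   {volume_l_kg: 0.0366, flow_ml_min_kg: 6.2,
            composition: {f_ew: 0.161, f_iw: 0.573, f_nl: 0.0140, f_np: 0.0240, ap_mg_g: 4.56}}
  rest:    {volume_l_kg: 0.0890, flow_ml_min_kg: 21.0,
            composition: {f_ew: 0.150, f_iw: 0.626, f_nl: 0.0170, f_np: 0.0092, ap_mg_g: 2.30}}
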