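# Human (60 kg reference adult) whole-body physiology for a perfusion-limited
# PBPK model.  Volumes and regional flows from standard physiological
# reference compilations, scaled to a 60 kg body weight; tissue composition
# is taken from the same composition tables as the rat file (composition is
# assumed conserved across species -- see the methods note).
# Total hepatic blood flow is 5.4+12+2+1.3 = 20.7 mL/min/kg.
species: human
body_weight_kg: 60.0
hematocrit: 0.45
cardiac_output_ml_min_kg: 83.3
gfr_ml_min_kg: 1.8
ph:
  plasma: 7.4
  intracellular: 7.0
  erythrocyte: 7.22
blood:
  arterial_volume_l_kg: 0.0257
  venous_volume_l_kg: 0.0533
erythrocyte_composition: {f_iw: 0.603, f_nl: 0.0017, f_np: 0.0029, ap_mg_g: 0.5}
organs:
  lung:    {volume_l_kg: 0.0076, flow_ml_min_kg: 83.3,
            composition: {f_ew: 0.336, f_iw: 0.446, f_nl: 0.0220, f_np: 0.0128, ap_mg_g: 3.91}}
  adipose: {volume_l_kg: 0.1900, flow_ml_min_kg: 4.17,
            composition: {f_ew: 0.135, f_iw: 0.017, f_nl: 0.8530, f_np: 0.0016, ap_mg_g: 0.40}}
  bone:    {volume_l_kg: 0.0860, flow_ml_min_kg: 4.17,
            composition: {f_ew: 0.100, f_iw: 0.346, f_nl: 0.0170, f_np: 0.0017, ap_mg_g: 0.67}}
  brain:   {volume_l_kg: 0.0230, flow_ml_min_kg: 10.0,
            composition: {f_ew: 0.162, f_iw: 0.620, f_nl: 0.0390, f_np: 0.0015, ap_mg_g: 0.40}}
  heart:   {volume_l_kg: 0.0047, flow_ml_min_kg: 3.33,
            composition: {f_ew: 0.320, f_iw: 0.456, f_nl: 0.0140, f_np: 0.0111, ap_mg_g: 2.25}}
  kidney:  {volume_l_kg: 0.0044, flow_ml_min_kg: 15.8,
            composition: {f_ew: 0.273, f_iw: 0.483, f_nl: 0.0120, f_np: 0.0242, ap_mg_g: 5.03}}
  muscle:  {volume_l_kg: 0.4000, flow_ml_min_kg: 14.2,
            composition: {f_ew: 0.118, f_iw: 0.630, f_nl: 0.0100, f_np: 0.0072, ap_mg_g: 1.53}}
  skin:    {volume_l_kg: 0.0370, flow_ml_min_kg: 4.17,
            composition: {f_ew: 0.382, f_iw: 0.291, f_nl: 0.0600, f_np: 0.0044, ap_mg_g: 1.32}}
  gut:     {volume_l_kg: 0.0170, flow_ml_min_kg: 12.0,
            composition: {f_ew: 0.282, f_iw: 0.475, f_nl: 0.0380, f_np: 0.0125, ap_mg_g: 2.41}}
  spleen:  {volume_l_kg: 0.0026, flow_ml_min_kg: 2.0,
            composition: {f_ew: 0.207, f_iw: 0.579, f_nl: 0.0077, f_np: 0.0113, ap_mg_g: 3.18}}
  stomach: {volume_l_kg: 0.0021, flow_ml_min_kg: 1.3,
            composition: {f_ew: 0.282, f_iw: 0.475, f_nl: 0.0380, f_np: 0.0125, ap_mg_g: 2.41}}
  gonads:  {volume_l_kg: 0.0006, flow_ml_min_kg: 0.05,
            composition: {f_ew: 0.150, f_iw: 0.626, f_nl: 0.0170, f_np: 0.0092, ap_mg_g: 2.30}}
  liver:   {volume_l_kg: 0.0260, flow_ml_min_kg: 5.4,
            composition: {f_ew: 0.161, f_iw: 0.573, f_nl: 0.0140, f_np: 0.0240, ap_mg_g: 4.56}}
  rest:    {volume_l_kg: 0.1190, flow_ml_min_kg: 6.71,
            composition: {f_ew: 0.150, f_iw: 0.626, f_nl: 0.0170, f_np: 0.0092, ap_mg_g: 2.30}}
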