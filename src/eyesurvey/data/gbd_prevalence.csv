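# Published planning estimates for school-age children (6-17 years), by Global
# Burden of Disease (GBD) super region.
#
# kind=services: estimated percentage of children requiring services for eye
#   conditions in the two super regions with the highest and lowest estimates;
#   vision_impairment_total + non_vision_impairing = all_conditions.
# kind=vi_range: lowest/highest published prevalence of vision impairment per
#   super region (presenting visual acuity at or below roughly 6/12 in the
#   better eye; threshold varies slightly by source study).
label,region,condition_group,kind,prevalence_percent
SEA-EA-O all causes of vision impairment needing services,"South-East Asia, East Asia & Oceania",vision_impairment_total,services,17.0
SEA-EA-O vision impairment due to uncorrected refractive error,"South-East Asia, East Asia & Oceania",vision_impairment_ure,services,16.5
SEA-EA-O non-vision impairing eye conditions,"South-East Asia, East Asia & Oceania",non_vision_impairing,services,1.9
SEA-EA-O all eye conditions needing services,"South-East Asia, East Asia & Oceania",all_conditions,services,18.9
SSA all causes of vision impairment needing services,Sub-Saharan Africa,vision_impairment_total,services,2.0
SSA vision impairment due to uncorrected refractive error,Sub-Saharan Africa,vision_impairment_ure,services,0.9
SSA non-vision impairing eye conditions,Sub-Saharan Africa,non_vision_impairing,services,1.9
SSA all eye conditions needing services,Sub-Saharan Africa,all_conditions,services,3.9
CEEECA vision impairment range low,"Central Europe, Eastern Europe & Central Asia",vision_impairment_low,vi_range,1.9
CEEECA vision impairment range high,"Central Europe, Eastern Europe & Central Asia",vision_impairment_high,vi_range,17.0
High Income vision impairment range low,High Income,vision_impairment_low,vi_range,1.2
High Income vision impairment range high,High Income,vision_impairment_high,vi_range,5.2
LAC vision impairment range low,Latin America & Caribbean,vision_impairment_low,vi_range,5.8
LAC vision impairment range high,Latin America & Caribbean,vision_impairment_high,vi_range,12.8
NAME vision impairment range low,North Africa & Middle East,vision_impairment_low,vi_range,2.7
NAME vision impairment range high,North Africa & Middle East,vision_impairment_high,vi_range,8.9
South Asia vision impairment range low,South Asia,vision_impairment_low,vi_range,1.49
South Asia vision impairment range high,South Asia,vision_impairment_high,vi_range,1.7
SEA-EA-O vision impairment range low,"South-East Asia, East Asia & Oceania",vision_impairment_low,vi_range,5.9
SSA vision impairment range low,Sub-Saharan Africa,vision_impairment_low,vi_range,3.4
SSA vision impairment range high,Sub-Saharan Africa,vision_impairment_high,vi_range,3.93
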