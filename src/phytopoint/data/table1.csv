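parameter,automated,manual,unit
height,27.7,28.0,cm
width,45.1,45.5,cm
hull_area,3635,,cm2
hull_volume,16107,,cm3
leaf_area,809,,cm2
projected_leaf_area,522,,cm2
leaf_count,,12,count
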