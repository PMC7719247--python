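climate_zone,soil_class,soc_ref_mg_c_ha
boreal-dry,high-activity-mineral,68
boreal-dry,sandy,10
boreal-dry,spodic,117
boreal-dry,volcanic,20
boreal-dry,wetland,146
boreal-moist,high-activity-mineral,68
boreal-moist,sandy,10
boreal-moist,spodic,117
boreal-moist,volcanic,20
boreal-moist,wetland,146
cold-temperate-dry,high-activity-mineral,50
cold-temperate-dry,low-activity-mineral,33
cold-temperate-dry,sandy,34
cold-temperate-dry,volcanic,20
cold-temperate-dry,wetland,87
cold-temperate-moist,high-activity-mineral,95
cold-temperate-moist,low-activity-mineral,85
cold-temperate-moist,sandy,71
cold-temperate-moist,spodic,115
cold-temperate-moist,volcanic,130
cold-temperate-moist,wetland,87
warm-temperate-dry,high-activity-mineral,38
warm-temperate-dry,low-activity-mineral,24
warm-temperate-dry,sandy,19
warm-temperate-dry,volcanic,70
warm-temperate-dry,wetland,88
warm-temperate-moist,high-activity-mineral,88
warm-temperate-moist,low-activity-mineral,63
warm-temperate-moist,sandy,34
warm-temperate-moist,volcanic,80
warm-temperate-moist,wetland,88
tropical-dry,high-activity-mineral,38
tropical-dry,low-activity-mineral,35
tropical-dry,sandy,31
tropical-dry,volcanic,50
tropical-dry,wetland,86
tropical-moist,high-activity-mineral,65
tropical-moist,low-activity-mineral,47
tropical-moist,sandy,39
tropical-moist,volcanic,70
tropical-moist,wetland,86
tropical-wet,high-activity-mineral,44
tropical-wet,low-activity-mineral,60
tropical-wet,sandy,66
tropical-wet,volcanic,130
tropical-wet,wetland,86
tropical-montane,high-activity-mineral,88
tropical-montane,low-activity-mineral,63
tropical-montane,sandy,34
tropical-montane,volcanic,80
tropical-montane,wetland,86
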