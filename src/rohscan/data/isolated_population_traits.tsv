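population	max_length_mm	age1_length_mm	growth_age1_age2_mm
Camas	211	62	44
MagpieSpring	197	58	38
Wolf	229	50	37
Sixmile	215	48	39
Teepee	220	58	44
TalkingWater	191	55	56
Cooney	276	52	51
Cold	256	53	41
Frog	175	46	33
SouthForkDavis	180	48	38
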