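taxon_std,b0,b1
Ash,-2.10,2.45
Basswood,-2.45,2.50
Beech,-2.00,2.45
Birch,-2.20,2.45
Black gum/sweet gum,-2.30,2.45
Cedar/juniper,-2.60,2.40
Cherry,-2.20,2.40
Dogwood,-2.30,2.40
Elm,-2.15,2.45
Fir,-2.70,2.45
Hemlock,-2.55,2.45
Hickory,-1.95,2.50
Ironwood,-2.10,2.40
Maple,-2.05,2.45
Oak,-2.00,2.50
Pine,-2.60,2.45
Poplar/tulip poplar,-2.45,2.45
Spruce,-2.65,2.45
Tamarack,-2.55,2.40
Walnut,-2.10,2.45
Other hardwood,-2.20,2.45
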