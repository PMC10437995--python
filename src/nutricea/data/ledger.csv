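label,category,unit_cost,quantity,amount,attributable_fraction
"Personnel: management, supervision and village health workers",personnel,,,46485,1
"Food demonstration sessions",materials_other,14.50,150,,1
"Other materials, transport, incentives and refreshments",materials_other,,,9321,1
"Capacity building: recruitment and training of health workers",capacity_building,,,1822,1
"Capital: assessment rooms, mobile tent and phones",capital,,,533,1
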