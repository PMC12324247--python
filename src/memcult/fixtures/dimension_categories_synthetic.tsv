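dimension	category
Animal/organic	life
Arms/skin	life
Head/face	life
Plant/green	life
Disgusting/bugs	life
Food/eating	life
Body/limbs	life
Bird/feather	life
Fish/aquatic	life
Fur/pet	life
Flower/petal	life
Metal/artificial	nonlife
Fire/heat	nonlife
Long/thin	nonlife
Tool/hammer	nonlife
Musical/noise	nonlife
Bathroom/sanitary	nonlife
Grating/metal	nonlife
Container/hollow	nonlife
Weapon/danger	nonlife
Clothing/fabric	nonlife
Seating/put	nonlife
Construction/work	nonlife
Wood/brownish	nonlife
Furniture/household	nonlife
Red	nonlife
String/rope	nonlife
Shiny/transparent	nonlife
Electronic/technology	nonlife
Vehicle/transport	nonlife
Paper/flat	nonlife
Round/circular	nonlife
Box/rectangular	nonlife
Kitchen/cooking	nonlife
Stationery/office	nonlife
Toy/plaything	nonlife
Light/lamp	nonlife
Footwear/shoe	nonlife
Sports/game	nonlife
Decorative/ornament	nonlife
Powder/granular	nonlife
Soft/cushion	nonlife
White/pale	nonlife
Black/dark	nonlife
Sky/flying	mixed
Outdoors/nature	mixed
Water/liquid	mixed
Ground/soil	mixed
Medicine/health	mixed
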