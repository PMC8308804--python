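item_id	label	nova	iarc	ific	unc	note
orange	orange	1	1	1	1	
apple	apple	1	1	1	1	
banana	banana	1	1	1	1	
pear	pear	1	1	1	1	
peach	peach	1	1	1	1	
grapes	grapes	1	1	1	1	
melon	melon	1	1	1	1	
watermelon	watermelon	1	1	1	1	
strawberries	strawberries	1	1	1	1	
kiwi	kiwi	1	1	1	1	
cherries	cherries	1	1	1	1	
figs	figs	1	1	1	1	
mandarin	mandarin	1	1	1	1	
plum	plum	1	1	1	1	
apricot	apricot	1	1	1	1	
pineapple_fresh	pineapple fresh	1	1	1	1	
avocado	avocado	1	1	1	1	
pomegranate	pomegranate	1	1	1	1	
grapefruit	grapefruit	1	1	1	1	
loquat	loquat	1	1	1	1	
lettuce	lettuce	1	1	1	1	assumed consumed raw
tomato_raw	tomato, raw	1	1	1	1	
cucumber	cucumber	1	1	1	1	
walnuts	walnuts	1	1	1	1	assumed natural with no additions
raisins	raisins	1	1	1	1	assumed without added sugar
cabbage	cabbage	1	2	2	2	assumed cooked in a basic manner
carrot_cooked	carrot cooked	1	2	2	2	assumed cooked in a basic manner
peas	peas	1	2	2	2	assumed cooked in a basic manner
pumpkin	pumpkin	1	2	2	2	assumed cooked in a basic manner
zucchini	zucchini	1	2	2	2	assumed cooked in a basic manner
garlic	garlic	1	2	2	2	assumed cooked in a basic manner
onion	onion	1	2	2	2	assumed cooked in a basic manner
green_beans	green beans	1	2	2	2	
spinach	spinach	1	2	2	2	
chard	chard	1	2	2	2	
cauliflower	cauliflower	1	2	2	2	
eggplant	eggplant	1	2	2	2	
mushrooms	mushrooms	1	2	2	2	
potato_boiled	potato, boiled	1	2	2	2	
lentils	lentils	1	2	2	2	assumed cooked in a basic manner
chickpeas	chickpeas	1	2	2	2	assumed cooked in a basic manner
white_beans	white beans	1	2	2	2	assumed cooked in a basic manner
eggs	eggs	1	2	2	2	assumed cooked in a basic manner
chicken	chicken	1	2	2	2	assumed raw or cooked in a basic manner
beef	beef	1	2	2	2	assumed raw or cooked in a basic manner
pork_loin	pork loin	1	2	2	2	assumed raw or cooked in a basic manner
lamb	lamb	1	2	2	2	assumed raw or cooked in a basic manner
hake	hake	1	2	2	2	assumed raw or cooked in a basic manner
sardine_fresh	sardine fresh	1	2	2	2	assumed raw or cooked in a basic manner
tuna_fresh	tuna fresh	1	2	2	2	assumed raw or cooked in a basic manner
cod_fresh	cod fresh	1	2	2	2	assumed raw or cooked in a basic manner
rice	rice	1	2	2	2	
pasta	pasta	1	2	2	2	
bread_white	bread, white	3	3	3	3.2	assumed freshly baked and not packaged
bread_whole	bread, wholemeal	3	3	3	3.2	assumed freshly baked and not packaged
olive_oil_virgin	olive oil, virgin	2	3	3	3.1	
olive_oil_refined	olive oil, refined	2	3	3	3.1	
sunflower_oil	sunflower oil	2	3	3	3.1	
sugar	sugar, white	2	3	3	3.1	
honey	honey	2	3	3	3.1	
butter_salted	butter	2	3	3	3.1	assumed salted
cheese_cured	cheese, cured	3	3	3	3.1	
cheese_semicured	cheese, semi-cured	3	3	3	3.1	
cheese_goat	cheese, goat	3	3	3	3.1	
tuna_canned	tuna, canned	3	3	3	3.1	
sardines_canned	sardines, canned	3	3	3	3.1	
mussels_canned	mussels, canned	3	3	3	3.1	
asparagus_canned	asparagus, canned	3	3	3	3.1	assumed canned and of the white type
tomato_canned	tomato, canned natural	3	3	3	3.1	
corn_canned	sweetcorn, canned	3	3	3	3.1	
pickles	gherkins and pickles	3	3	3	3.1	
olives_table	olives, table	3	3	3	3.1	
ham_cured	ham, cured	3	3	3	3.1	
chorizo	chorizo	3	3	3	3.1	
salchichon	salchichon / salami	3	3	3	3.1	
bacon	bacon	3	3	3	3.1	
lard	lard	2	3	3	3.1	
anchovies_salted	anchovies, salted	3	3	3	3.1	
cod_salted	cod, salted	3	3	3	3.1	
smoked_salmon	salmon, smoked	3	3	3	3.1	
quince_paste	quince paste	3	3	3	3.2	
dried_apricots	apricots, dried	3	3	3	3.2	
almonds_toasted	almonds, toasted	3	3	3	3.2	assumed toasted without salt
pistachios	pistachios	3	3	3	3.2	assumed salted
nuts_salted	other nuts, salted or roasted	3	3	3	3.2	assumed salted and/or roasted
muesli	muesli	3	3	3	3.2	wholegrain cereals with no added sugar
breadsticks	breadsticks	3	3	3	3.2	
wine_red	wine, red	3	3	3	3.2	
wine_white	wine, white	3	3	3	3.2	
beer	beer	3	3	3	3.2	
vermouth	vermouth	3	3	3	3.2	
coffee	coffee, ground	3	3	3	3.2	assumed roasted ground beans, not soluble
milk_whole	milk, whole (UHT)	1	3	4	4.1	assumed processed using ultra-heated temperature
milk_semi	milk, semi-skimmed (UHT)	1	3	4	4.1	assumed processed using ultra-heated temperature
milk_skim	milk, skimmed (UHT)	1	3	4	4.1	assumed processed using ultra-heated temperature
yogurt_natural	yogurt, natural	1	3	4	4.1	
cheese_fresh	cheese, fresh	1	3	4	3.1	
peaches_syrup	peaches in syrup, canned	3	3	3	4.2	
cola	cola drinks	4	3	5	4.2	
orange_soda	orange soft drink	4	3	5	4.2	
lemon_soda	lemon soft drink	4	3	5	4.2	
juice_packaged	fruit juice, packaged	4	3	4	4.1	
milkshake	milkshake	4	3	5	4.2	assumed industrially produced
cheese_wedges	cheese wedges, soft	4	3	5	4.2	assumed industrially produced
custard	custard	4	3	5	4.2	assumed industrially produced
ice_cream	ice cream	4	3	5	4.2	assumed industrially produced
cookies_maria	biscuits, plain (maria)	4	3	4	4.1	
cookies_chocolate	biscuits, chocolate	4	3	5	4.2	
croissant	croissant	4	3	5	4.2	
donut	doughnut	4	3	5	4.2	
muffin	muffin (magdalena)	4	3	4	4.1	
sponge_cake	sponge cake	4	3	4	4.1	
chocolate_bar	chocolate	4	3	5	4.2	
cocoa_powder	cocoa powder, sweetened	4	3	5	4.2	
candies	candies and sweets	4	3	5	4.2	
nougat	nougat (turron)	4	3	4	4.1	
jam	jam	4	3	4	4.1	
breakfast_cereals	breakfast cereals	4	3	5	4.2	
sliced_bread	sliced bread, packaged	4	3	4	4.1	
frankfurter	frankfurter sausage	4	3	5	4.2	
mortadella	mortadella and fiambres	4	3	5	4.2	
cooked_ham	ham, cooked	4	3	4	4.1	
pate	pate	4	3	5	4.2	
nuggets	chicken nuggets	4	3	5	4.2	
pizza	pizza	4	3	5	4.2	
croquettes	croquettes, frozen	4	3	4	4.1	
french_fries	french fries, frozen	4	3	4	4.1	
potato_chips	potato chips	4	3	5	4.2	
instant_soup	instant soup	4	3	5	4.2	
ketchup	ketchup	4	3	5	4.2	
mayonnaise	mayonnaise, industrial	4	3	4	4.1	
margarine	margarine	4	3	4	4.1	
yogurt_sweetened	yogurt, sweetened or flavored	4	3	4	4.1	
flan	flan, packaged	4	3	4	4.1	
whisky	spirits (whisky, gin, rum)	4	3	4	4.2	
mineral_water	mineral water					not allocated to a processing group
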