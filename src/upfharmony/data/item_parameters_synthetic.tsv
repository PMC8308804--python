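item_id	portion_g	mean_g_per_day	zero_prob	sigma	loading
orange	225	57.6	0.1	0.7	-0.35
apple	185	44.800000000000004	0.1	0.7	-0.35
banana	120	27.200000000000003	0.1	0.7	-0.35
pear	170	30.400000000000002	0.1	0.7	-0.35
peach	150	20.8	0.1	0.7	-0.35
grapes	150	12.0	0.1	0.7	-0.35
melon	250	30.400000000000002	0.1	0.7	-0.35
watermelon	250	30.400000000000002	0.1	0.7	-0.35
strawberries	150	9.600000000000001	0.1	0.7	-0.35
kiwi	90	12.0	0.1	0.7	-0.35
cherries	120	6.4	0.1	0.7	-0.35
figs	100	4.0	0.1	0.7	-0.35
mandarin	130	25.6	0.1	0.7	-0.35
plum	95	6.4	0.1	0.7	-0.35
apricot	100	4.800000000000001	0.1	0.7	-0.35
pineapple_fresh	140	6.4	0.1	0.7	-0.35
avocado	90	4.800000000000001	0.1	0.7	-0.35
pomegranate	150	3.2	0.1	0.7	-0.35
grapefruit	200	3.2	0.1	0.7	-0.35
loquat	120	2.4000000000000004	0.1	0.7	-0.35
lettuce	60	20.0	0.05	0.6	-0.3
tomato_raw	120	52.0	0.05	0.6	-0.3
cucumber	80	9.600000000000001	0.2	0.6	-0.3
walnuts	25	4.800000000000001	0.3	0.8	-0.3
raisins	25	1.6	0.55	0.8	-0.2
cabbage	100	12.0	0.08	0.6	-0.2
carrot_cooked	80	24.0	0.08	0.6	-0.2
peas	80	9.600000000000001	0.08	0.6	-0.2
pumpkin	120	8.0	0.08	0.6	-0.2
zucchini	120	22.400000000000002	0.08	0.6	-0.2
garlic	6	2.4000000000000004	0.08	0.6	-0.2
onion	60	28.0	0.08	0.6	-0.2
green_beans	120	28.0	0.08	0.6	-0.2
spinach	110	14.4	0.08	0.6	-0.2
chard	120	14.4	0.08	0.6	-0.2
cauliflower	130	12.0	0.08	0.6	-0.2
eggplant	120	9.600000000000001	0.08	0.6	-0.2
mushrooms	90	8.0	0.08	0.6	-0.2
potato_boiled	150	59.2	0.05	0.6	-0.1
lentils	150	17.6	0.08	0.6	-0.15
chickpeas	150	16.0	0.08	0.6	-0.15
white_beans	150	11.200000000000001	0.08	0.6	-0.15
eggs	60	28.0	0.03	0.5	-0.05
chicken	120	49.6	0.05	0.6	-0.05
beef	120	24.0	0.05	0.6	-0.05
pork_loin	120	20.0	0.05	0.6	-0.05
lamb	120	9.600000000000001	0.05	0.6	-0.05
hake	125	35.2	0.08	0.6	-0.1
sardine_fresh	125	16.0	0.08	0.6	-0.1
tuna_fresh	125	14.4	0.08	0.6	-0.1
cod_fresh	125	12.8	0.08	0.6	-0.1
rice	150	43.2	0.03	0.5	-0.05
pasta	150	38.400000000000006	0.03	0.5	0.0
bread_white	40	80.0	0.04	0.6	0.1
bread_whole	40	32.0	0.25	0.7	-0.1
olive_oil_virgin	10	25.6	0.03	0.5	-0.1
olive_oil_refined	10	6.4	0.35	0.7	0.05
sunflower_oil	10	4.800000000000001	0.35	0.7	0.1
sugar	8	8.0	0.25	0.8	0.15
honey	15	4.800000000000001	0.4	0.8	-0.05
butter_salted	12	2.4000000000000004	0.45	0.8	0.15
cheese_cured	40	12.0	0.15	0.7	0.1
cheese_semicured	40	9.600000000000001	0.2	0.7	0.1
cheese_goat	40	3.2	0.45	0.8	0.05
tuna_canned	55	11.200000000000001	0.15	0.6	0.1
sardines_canned	55	4.800000000000001	0.35	0.7	0.1
mussels_canned	50	2.4000000000000004	0.5	0.8	0.1
asparagus_canned	60	4.0	0.4	0.7	0.05
tomato_canned	80	9.600000000000001	0.25	0.7	0.1
corn_canned	60	3.2	0.45	0.8	0.1
pickles	30	2.4000000000000004	0.5	0.8	0.1
olives_table	25	5.6000000000000005	0.25	0.7	0.05
ham_cured	50	12.8	0.1	0.6	0.1
chorizo	40	5.6000000000000005	0.3	0.7	0.2
salchichon	40	4.0	0.35	0.7	0.2
bacon	50	3.2	0.45	0.8	0.25
lard	10	0.8	0.7	0.9	0.15
anchovies_salted	30	2.4000000000000004	0.5	0.8	0.05
cod_salted	80	4.800000000000001	0.4	0.8	-0.05
smoked_salmon	50	3.2	0.5	0.8	0.05
quince_paste	30	2.4000000000000004	0.55	0.8	0.05
dried_apricots	30	1.6	0.6	0.8	-0.1
almonds_toasted	25	4.800000000000001	0.3	0.8	-0.2
pistachios	25	1.6	0.55	0.8	0.1
nuts_salted	25	2.4000000000000004	0.45	0.8	0.15
muesli	40	2.4000000000000004	0.6	0.9	-0.1
breadsticks	25	3.2	0.45	0.8	0.15
wine_red	125	48.0	0.35	0.9	0.1
wine_white	125	20.0	0.5	0.9	0.1
beer	330	57.6	0.4	1.0	0.2
vermouth	70	3.2	0.65	0.9	0.15
coffee	50	65.60000000000001	0.15	0.7	0.1
milk_whole	200	64.0	0.3	0.8	0.05
milk_semi	200	84.0	0.25	0.8	0.0
milk_skim	200	36.800000000000004	0.45	0.9	-0.05
yogurt_natural	125	38.400000000000006	0.2	0.8	-0.05
cheese_fresh	60	12.0	0.25	0.7	0.0
peaches_syrup	100	6.4	0.4	0.8	0.1
cola	330	11.200000000000001	0.55	1.0	0.65
orange_soda	330	4.800000000000001	0.65	1.0	0.65
lemon_soda	330	4.0	0.7	1.0	0.65
juice_packaged	200	10.4	0.5	0.9	0.5
milkshake	200	2.4000000000000004	0.7	0.9	0.6
cheese_wedges	25	3.2	0.45	0.8	0.45
custard	130	6.4	0.45	0.8	0.55
ice_cream	100	4.800000000000001	0.45	0.8	0.5
cookies_maria	30	6.4	0.35	0.8	0.5
cookies_chocolate	30	3.2	0.55	0.9	0.6
croissant	60	3.2	0.5	0.8	0.55
donut	50	2.4000000000000004	0.6	0.9	0.6
muffin	40	4.0	0.45	0.8	0.55
sponge_cake	50	3.2	0.55	0.9	0.55
chocolate_bar	20	3.2	0.45	0.9	0.5
cocoa_powder	12	1.6	0.65	0.9	0.45
candies	10	1.2000000000000002	0.7	0.9	0.55
nougat	30	1.6	0.6	0.9	0.45
jam	20	3.2	0.5	0.8	0.35
breakfast_cereals	30	4.0	0.55	0.9	0.5
sliced_bread	30	7.2	0.55	0.9	0.55
frankfurter	50	4.0	0.5	0.8	0.6
mortadella	40	3.2	0.5	0.8	0.6
cooked_ham	40	6.4	0.35	0.8	0.45
pate	25	1.6	0.65	0.9	0.55
nuggets	80	2.4000000000000004	0.65	0.9	0.6
pizza	150	5.6000000000000005	0.45	0.8	0.55
croquettes	90	4.0	0.55	0.8	0.55
french_fries	100	4.800000000000001	0.5	0.8	0.55
potato_chips	30	3.2	0.5	0.9	0.55
instant_soup	200	2.4000000000000004	0.7	0.9	0.5
ketchup	12	1.2000000000000002	0.65	0.9	0.55
mayonnaise	15	2.4000000000000004	0.5	0.8	0.45
margarine	12	1.6	0.6	0.9	0.45
yogurt_sweetened	125	12.0	0.4	0.9	0.5
flan	110	4.0	0.5	0.8	0.5
whisky	45	2.4000000000000004	0.7	1.0	0.4
mineral_water	250	320.0	0.3	0.8	0.0
tap_water	250	360.0	0.25	0.8	0.0
herbal_infusions	200	44.0	0.5	1.0	-0.1
saccharin	1	0.16000000000000003	0.75	0.9	0.1
table_salt	2	2.4000000000000004	0.1	0.6	0.1
vitamin_supplement	2	0.24	0.8	0.9	-0.05
protein_supplement	10	0.16000000000000003	0.92	0.9	0.0
royal_jelly	2	0.08000000000000002	0.93	0.9	-0.05
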