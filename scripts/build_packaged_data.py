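"""Build the packaged synthetic data tables.

Emits three TSVs under src/upfharmony/data/:
  taxonomy_synthetic.tsv        item -> processing group per system
  composition_synthetic.tsv     nutrients per 100 g per item
  item_parameters_synthetic.tsv portion size + intake-model parameters per item

and prints calibration diagnostics: the expected cohort-mean UPF share per
system and the expected daily energy implied by the item means.

Design constraints baked in:
  * 136 taxonomy records, exactly one unallocated in every system, so the
    per-system item-fraction denominator is 135.
  * UPF item counts: NOVA 37, IARC 82, IFIC 42, UNC 42 (82/135 = 60.7%,
    37/135 = 27.4%, 42/135 = 31.1%).
  * NOVA's UPF set is a strict subset of IARC's; IFIC and UNC are NOVA's set
    plus five dairy-ish items each (four shared).
  * UPF-flagged items have higher SFA/sugar/sodium densities and less fiber
    than minimally processed items, by template construction.
"""

from __future__ import annotations

import csv
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "upfharmony" / "data"

# comp templates: protein, fat, sfa, mufa, pufa, carb, fiber, sugars,
# sodium_mg, omega3, gi, alcohol_g  (per 100 g)
T = {
    "fruit":      (0.7, 0.3, 0.05, 0.10, 0.10, 12.0, 2.2, 9.5, 2, 0.0, 40, 0),
    "rawveg":     (1.2, 0.2, 0.03, 0.06, 0.08, 3.5, 1.8, 2.2, 8, 0.0, 30, 0),
    "veg":        (1.8, 0.3, 0.05, 0.10, 0.10, 5.0, 2.6, 2.6, 20, 0.0, 35, 0),
    "legume":     (8.0, 0.7, 0.10, 0.15, 0.35, 16.0, 6.5, 0.5, 12, 0.0, 30, 0),
    "potato":     (2.0, 0.1, 0.02, 0.03, 0.04, 17.0, 1.8, 0.8, 6, 0.0, 60, 0),
    "egg":        (12.5, 10.0, 3.0, 4.0, 1.5, 0.7, 0.0, 0.7, 140, 0.05, 0, 0),
    "meat":       (20.0, 9.0, 3.5, 4.0, 1.0, 0.0, 0.0, 0.0, 70, 0.05, 0, 0),
    "fish":       (18.0, 5.0, 1.2, 1.5, 1.8, 0.0, 0.0, 0.0, 90, 0.90, 0, 0),
    "grain":      (4.0, 0.5, 0.10, 0.10, 0.25, 28.0, 1.2, 0.5, 2, 0.0, 55, 0),
    "nut":        (15.0, 52.0, 5.0, 32.0, 12.0, 7.0, 8.0, 4.0, 3, 0.6, 15, 0),
    "nut_salted": (15.0, 52.0, 5.5, 31.0, 12.0, 7.0, 7.5, 4.0, 420, 0.4, 15, 0),
    "driedfruit": (2.5, 0.5, 0.05, 0.10, 0.20, 65.0, 6.0, 58.0, 12, 0.0, 55, 0),
    "milk_whole": (3.1, 3.6, 2.3, 1.0, 0.10, 4.7, 0.0, 4.7, 44, 0.02, 30, 0),
    "milk_semi":  (3.2, 1.6, 1.0, 0.45, 0.05, 4.8, 0.0, 4.8, 45, 0.01, 30, 0),
    "milk_skim":  (3.3, 0.3, 0.18, 0.08, 0.02, 4.9, 0.0, 4.9, 46, 0.0, 30, 0),
    "yogurt":     (3.8, 3.0, 1.9, 0.90, 0.10, 5.0, 0.0, 5.0, 60, 0.01, 30, 0),
    "freshcheese": (12.0, 15.0, 9.0, 4.0, 0.60, 3.0, 0.0, 3.0, 300, 0.02, 0, 0),
    "curedcheese": (25.0, 32.0, 19.0, 9.0, 1.2, 1.5, 0.0, 0.5, 800, 0.05, 0, 0),
    "bread":      (8.5, 1.6, 0.30, 0.40, 0.70, 51.0, 3.5, 2.0, 500, 0.02, 70, 0),
    "bread_whole": (9.5, 2.0, 0.35, 0.45, 0.90, 43.0, 7.2, 2.0, 480, 0.03, 62, 0),
    "muesli":     (9.0, 6.0, 1.0, 2.0, 2.5, 62.0, 8.0, 12.0, 20, 0.1, 55, 0),
    "oil_olive":  (0.0, 99.9, 14.0, 73.0, 11.0, 0.0, 0.0, 0.0, 0, 0.6, 0, 0),
    "oil_sun":    (0.0, 99.9, 11.0, 28.0, 59.0, 0.0, 0.0, 0.0, 0, 0.1, 0, 0),
    "sugar":      (0.0, 0.0, 0.0, 0.0, 0.0, 100.0, 0.0, 100.0, 1, 0.0, 68, 0),
    "honey":      (0.4, 0.0, 0.0, 0.0, 0.0, 80.0, 0.0, 79.0, 5, 0.0, 60, 0),
    "butter":     (0.7, 82.0, 52.0, 24.0, 3.0, 0.6, 0.0, 0.6, 600, 0.2, 0, 0),
    "cannedfish": (24.0, 10.0, 2.0, 5.0, 2.5, 0.0, 0.0, 0.0, 420, 1.5, 0, 0),
    "saltfish":   (25.0, 4.0, 1.0, 1.2, 1.5, 0.0, 0.0, 0.0, 2500, 1.2, 0, 0),
    "curedmeat":  (28.0, 15.0, 6.0, 7.0, 1.5, 0.5, 0.0, 0.5, 1400, 0.05, 0, 0),
    "olives":     (1.0, 12.0, 2.0, 9.0, 1.0, 1.0, 3.0, 0.2, 1500, 0.05, 10, 0),
    "cannedveg":  (1.8, 0.3, 0.05, 0.10, 0.10, 4.0, 2.2, 2.0, 350, 0.0, 35, 0),
    "pickle":     (0.9, 0.2, 0.03, 0.05, 0.08, 2.5, 1.2, 1.5, 900, 0.0, 20, 0),
    "quince":     (0.4, 0.1, 0.02, 0.03, 0.03, 62.0, 1.8, 58.0, 15, 0.0, 55, 0),
    "wine":       (0.2, 0.0, 0.0, 0.0, 0.0, 2.0, 0.0, 0.6, 4, 0.0, 10, 10.5),
    "beer":       (0.5, 0.0, 0.0, 0.0, 0.0, 3.5, 0.0, 0.2, 5, 0.0, 60, 4.0),
    "vermouth":   (0.1, 0.0, 0.0, 0.0, 0.0, 12.0, 0.0, 11.0, 5, 0.0, 25, 15.0),
    "spirits":    (0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.0, 0.1, 1, 0.0, 0, 33.0),
    "coffee":     (0.1, 0.0, 0.0, 0.0, 0.0, 0.3, 0.0, 0.0, 1, 0.0, 0, 0),
    "soda":       (0.0, 0.0, 0.0, 0.0, 0.0, 10.5, 0.0, 10.5, 5, 0.0, 63, 0),
    "juice_pack": (0.3, 0.1, 0.01, 0.02, 0.03, 11.0, 0.2, 10.5, 4, 0.0, 50, 0),
    "pastry":     (6.0, 21.0, 9.0, 8.0, 3.0, 52.0, 1.8, 26.0, 380, 0.05, 60, 0),
    "cookie":     (7.0, 19.0, 9.0, 7.0, 2.5, 66.0, 2.5, 28.0, 420, 0.05, 64, 0),
    "chocolate":  (7.0, 31.0, 18.0, 10.0, 1.5, 56.0, 5.0, 50.0, 70, 0.05, 45, 0),
    "cocoa_sweet": (6.0, 4.0, 2.3, 1.3, 0.2, 80.0, 4.0, 72.0, 120, 0.0, 60, 0),
    "candy":      (0.1, 0.2, 0.1, 0.05, 0.05, 93.0, 0.0, 70.0, 30, 0.0, 70, 0),
    "turron":     (12.0, 30.0, 3.5, 19.0, 6.5, 50.0, 4.0, 45.0, 50, 0.2, 50, 0),
    "jam":        (0.4, 0.1, 0.02, 0.03, 0.03, 60.0, 1.0, 58.0, 20, 0.0, 55, 0),
    "cereal":     (8.0, 3.0, 1.0, 0.8, 1.0, 80.0, 4.0, 22.0, 600, 0.05, 75, 0),
    "sliced_bread": (8.0, 4.5, 1.0, 1.6, 1.7, 49.0, 3.0, 5.5, 520, 0.02, 72, 0),
    "procmeat":   (13.0, 25.0, 9.5, 11.0, 2.8, 2.5, 0.0, 1.0, 1100, 0.05, 0, 0),
    "readymeal":  (11.0, 12.0, 4.0, 5.0, 2.5, 26.0, 1.8, 3.0, 650, 0.05, 55, 0),
    "fries":      (4.0, 15.0, 3.0, 7.0, 4.5, 34.0, 3.2, 0.5, 350, 0.05, 62, 0),
    "chips":      (6.0, 33.0, 6.5, 15.0, 10.0, 50.0, 4.2, 0.6, 720, 0.05, 60, 0),
    "soup_inst":  (2.0, 1.5, 0.6, 0.6, 0.3, 8.0, 0.5, 1.5, 350, 0.0, 45, 0),
    "ketchup":    (1.2, 0.2, 0.03, 0.05, 0.08, 24.0, 0.5, 22.0, 900, 0.0, 50, 0),
    "mayo":       (1.1, 75.0, 11.0, 45.0, 17.0, 2.0, 0.0, 1.5, 600, 0.5, 0, 0),
    "margarine":  (0.2, 70.0, 18.0, 30.0, 20.0, 0.5, 0.0, 0.3, 700, 1.0, 0, 0),
    "dairy_dess": (3.5, 7.0, 4.5, 2.0, 0.3, 22.0, 0.2, 20.0, 90, 0.01, 50, 0),
    "fruit_syrup": (0.4, 0.1, 0.01, 0.02, 0.03, 19.0, 1.0, 18.0, 8, 0.0, 55, 0),
    "smoked":     (22.0, 11.0, 2.2, 4.5, 3.5, 0.0, 0.0, 0.5, 1600, 2.2, 0, 0),
    "water":      (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2, 0.0, 0, 0),
    "infusion":   (0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.0, 0.0, 1, 0.0, 0, 0),
    "supplement": (0.0, 0.0, 0.0, 0.0, 0.0, 0.5, 0.0, 0.0, 1, 0.0, 0, 0),
}

# item_id, label, nova, iarc, ific, unc, note, template, portion_g, mean_gd,
# zero_prob, sigma, loading
ITEMS = []


def add(item_id, label, nova, iarc, ific, unc, note, tmpl, portion, mean_gd,
        p0, sigma, loading):
    ITEMS.append((item_id, label, nova, iarc, ific, unc, note, tmpl, portion,
                  mean_gd, p0, sigma, loading))


# ---- group X1: fresh / minimally processed everywhere (25) -----------------
fruits = [
    ("orange", 225, 60), ("apple", 185, 45), ("banana", 120, 30),
    ("pear", 170, 30), ("peach", 150, 22), ("grapes", 150, 15),
    ("melon", 250, 30), ("watermelon", 250, 30), ("strawberries", 150, 12),
    ("kiwi", 90, 15), ("cherries", 120, 8), ("figs", 100, 5),
    ("mandarin", 130, 25), ("plum", 95, 8), ("apricot", 100, 6),
    ("pineapple_fresh", 140, 8), ("avocado", 90, 6), ("pomegranate", 150, 4),
    ("grapefruit", 200, 4), ("loquat", 120, 3),
]
for name, portion, mean in fruits:
    add(name, name.replace("_", " "), "1", "1", "1", "1", "", "fruit",
        portion, mean, 0.10, 0.7, -0.35)
add("lettuce", "lettuce", "1", "1", "1", "1",
    "assumed consumed raw", "rawveg", 60, 25, 0.05, 0.6, -0.30)
add("tomato_raw", "tomato, raw", "1", "1", "1", "1", "", "rawveg",
    120, 55, 0.05, 0.6, -0.30)
add("cucumber", "cucumber", "1", "1", "1", "1", "", "rawveg",
    80, 12, 0.20, 0.6, -0.30)
add("walnuts", "walnuts", "1", "1", "1", "1",
    "assumed natural with no additions", "nut", 25, 6, 0.30, 0.8, -0.30)
add("raisins", "raisins", "1", "1", "1", "1",
    "assumed without added sugar", "driedfruit", 25, 2, 0.55, 0.8, -0.20)

# ---- group X2: basic cooking, moderately processed for IARC (28) -----------
veg = [
    ("cabbage", 100, 15), ("carrot_cooked", 80, 25), ("peas", 80, 12),
    ("pumpkin", 120, 10), ("zucchini", 120, 22), ("garlic", 6, 3),
    ("onion", 60, 28), ("green_beans", 120, 28), ("spinach", 110, 18),
    ("chard", 120, 18), ("cauliflower", 130, 15), ("eggplant", 120, 12),
    ("mushrooms", 90, 10),
]
basic_cooked = {"cabbage", "carrot_cooked", "peas", "pumpkin", "zucchini",
               "garlic", "onion"}
for name, portion, mean in veg:
    note = "assumed cooked in a basic manner" if name in basic_cooked else ""
    add(name, name.replace("_", " "), "1", "2", "2", "2", note, "veg",
        portion, mean, 0.08, 0.6, -0.20)
add("potato_boiled", "potato, boiled", "1", "2", "2", "2", "", "potato",
    150, 65, 0.05, 0.6, -0.10)
for name, mean in [("lentils", 22), ("chickpeas", 20), ("white_beans", 14)]:
    add(name, name.replace("_", " "), "1", "2", "2", "2",
        "assumed cooked in a basic manner", "legume", 150, mean, 0.08, 0.6,
        -0.15)
add("eggs", "eggs", "1", "2", "2", "2", "assumed cooked in a basic manner",
    "egg", 60, 32, 0.03, 0.5, -0.05)
for name, mean in [("chicken", 55), ("beef", 30), ("pork_loin", 25),
                   ("lamb", 12)]:
    add(name, name.replace("_", " "), "1", "2", "2", "2",
        "assumed raw or cooked in a basic manner", "meat", 120, mean, 0.05,
        0.6, -0.05)
for name, mean in [("hake", 38), ("sardine_fresh", 20), ("tuna_fresh", 18),
                   ("cod_fresh", 16)]:
    add(name, name.replace("_", " "), "1", "2", "2", "2",
        "assumed raw or cooked in a basic manner", "fish", 125, mean, 0.08,
        0.6, -0.10)
add("rice", "rice", "1", "2", "2", "2", "", "grain", 150, 48, 0.03, 0.5, -0.05)
add("pasta", "pasta", "1", "2", "2", "2", "", "grain", 150, 42, 0.03, 0.5, 0.0)

# ---- group X3: processed; UPF only under IARC (39) -------------------------
add("bread_white", "bread, white", "3", "3", "3", "3.2",
    "assumed freshly baked and not packaged", "bread", 40, 105, 0.04, 0.6,
    0.10)
add("bread_whole", "bread, wholemeal", "3", "3", "3", "3.2",
    "assumed freshly baked and not packaged", "bread_whole", 40, 40, 0.25,
    0.7, -0.10)
add("olive_oil_virgin", "olive oil, virgin", "2", "3", "3", "3.1", "",
    "oil_olive", 10, 32, 0.03, 0.5, -0.10)
add("olive_oil_refined", "olive oil, refined", "2", "3", "3", "3.1", "",
    "oil_olive", 10, 8, 0.35, 0.7, 0.05)
add("sunflower_oil", "sunflower oil", "2", "3", "3", "3.1", "", "oil_sun",
    10, 6, 0.35, 0.7, 0.10)
add("sugar", "sugar, white", "2", "3", "3", "3.1", "", "sugar", 8, 10, 0.25,
    0.8, 0.15)
add("honey", "honey", "2", "3", "3", "3.1", "", "honey", 15, 6, 0.40, 0.8,
    -0.05)
add("butter_salted", "butter", "2", "3", "3", "3.1", "assumed salted",
    "butter", 12, 3, 0.45, 0.8, 0.15)
add("cheese_cured", "cheese, cured", "3", "3", "3", "3.1", "", "curedcheese",
    40, 15, 0.15, 0.7, 0.10)
add("cheese_semicured", "cheese, semi-cured", "3", "3", "3", "3.1", "",
    "curedcheese", 40, 12, 0.20, 0.7, 0.10)
add("cheese_goat", "cheese, goat", "3", "3", "3", "3.1", "", "curedcheese",
    40, 4, 0.45, 0.8, 0.05)
add("tuna_canned", "tuna, canned", "3", "3", "3", "3.1", "", "cannedfish",
    55, 14, 0.15, 0.6, 0.10)
add("sardines_canned", "sardines, canned", "3", "3", "3", "3.1", "",
    "cannedfish", 55, 6, 0.35, 0.7, 0.10)
add("mussels_canned", "mussels, canned", "3", "3", "3", "3.1", "",
    "cannedfish", 50, 3, 0.50, 0.8, 0.10)
add("asparagus_canned", "asparagus, canned", "3", "3", "3", "3.1",
    "assumed canned and of the white type", "cannedveg", 60, 5, 0.40, 0.7,
    0.05)
add("tomato_canned", "tomato, canned natural", "3", "3", "3", "3.1", "",
    "cannedveg", 80, 12, 0.25, 0.7, 0.10)
add("corn_canned", "sweetcorn, canned", "3", "3", "3", "3.1", "", "cannedveg",
    60, 4, 0.45, 0.8, 0.10)
add("pickles", "gherkins and pickles", "3", "3", "3", "3.1", "", "pickle",
    30, 3, 0.50, 0.8, 0.10)
add("olives_table", "olives, table", "3", "3", "3", "3.1", "", "olives",
    25, 7, 0.25, 0.7, 0.05)
add("ham_cured", "ham, cured", "3", "3", "3", "3.1", "", "curedmeat", 50, 16,
    0.10, 0.6, 0.10)
add("chorizo", "chorizo", "3", "3", "3", "3.1", "", "curedmeat", 40, 7, 0.30,
    0.7, 0.20)
add("salchichon", "salchichon / salami", "3", "3", "3", "3.1", "", "curedmeat",
    40, 5, 0.35, 0.7, 0.20)
add("bacon", "bacon", "3", "3", "3", "3.1", "", "curedmeat", 50, 4, 0.45,
    0.8, 0.25)
add("lard", "lard", "2", "3", "3", "3.1", "", "butter", 10, 1, 0.70, 0.9,
    0.15)
add("anchovies_salted", "anchovies, salted", "3", "3", "3", "3.1", "",
    "saltfish", 30, 3, 0.50, 0.8, 0.05)
add("cod_salted", "cod, salted", "3", "3", "3", "3.1", "", "saltfish", 80, 6,
    0.40, 0.8, -0.05)
add("smoked_salmon", "salmon, smoked", "3", "3", "3", "3.1", "", "smoked",
    50, 4, 0.50, 0.8, 0.05)
add("quince_paste", "quince paste", "3", "3", "3", "3.2", "", "quince", 30, 3,
    0.55, 0.8, 0.05)
add("dried_apricots", "apricots, dried", "3", "3", "3", "3.2", "",
    "driedfruit", 30, 2, 0.60, 0.8, -0.10)
add("almonds_toasted", "almonds, toasted", "3", "3", "3", "3.2",
    "assumed toasted without salt", "nut", 25, 6, 0.30, 0.8, -0.20)
add("pistachios", "pistachios", "3", "3", "3", "3.2", "assumed salted",
    "nut_salted", 25, 2, 0.55, 0.8, 0.10)
add("nuts_salted", "other nuts, salted or roasted", "3", "3", "3", "3.2",
    "assumed salted and/or roasted", "nut_salted", 25, 3, 0.45, 0.8, 0.15)
add("muesli", "muesli", "3", "3", "3", "3.2",
    "wholegrain cereals with no added sugar", "muesli", 40, 3, 0.60, 0.9,
    -0.10)
add("breadsticks", "breadsticks", "3", "3", "3", "3.2", "", "bread", 25, 4,
    0.45, 0.8, 0.15)
add("wine_red", "wine, red", "3", "3", "3", "3.2", "", "wine", 125, 65, 0.35,
    0.9, 0.10)
add("wine_white", "wine, white", "3", "3", "3", "3.2", "", "wine", 125, 25,
    0.50, 0.9, 0.10)
add("beer", "beer", "3", "3", "3", "3.2", "", "beer", 330, 80, 0.40, 1.0,
    0.20)
add("vermouth", "vermouth", "3", "3", "3", "3.2", "", "vermouth", 70, 4, 0.65,
    0.9, 0.15)
add("coffee", "coffee, ground", "3", "3", "3", "3.2",
    "assumed roasted ground beans, not soluble", "coffee", 50, 85, 0.15, 0.7,
    0.10)

# ---- group X4: dairy-style divergence items (6) ----------------------------
add("milk_whole", "milk, whole (UHT)", "1", "3", "4", "4.1",
    "assumed processed using ultra-heated temperature", "milk_whole", 200, 85,
    0.30, 0.8, 0.05)
add("milk_semi", "milk, semi-skimmed (UHT)", "1", "3", "4", "4.1",
    "assumed processed using ultra-heated temperature", "milk_semi", 200, 110,
    0.25, 0.8, 0.0)
add("milk_skim", "milk, skimmed (UHT)", "1", "3", "4", "4.1",
    "assumed processed using ultra-heated temperature", "milk_skim", 200, 50,
    0.45, 0.9, -0.05)
add("yogurt_natural", "yogurt, natural", "1", "3", "4", "4.1", "", "yogurt",
    125, 50, 0.20, 0.8, -0.05)
add("cheese_fresh", "cheese, fresh", "1", "3", "4", "3.1", "", "freshcheese",
    60, 15, 0.25, 0.7, 0.0)
add("peaches_syrup", "peaches in syrup, canned", "3", "3", "3", "4.2", "",
    "fruit_syrup", 100, 8, 0.40, 0.8, 0.10)

# ---- group A: ultra-processed under NOVA (37) ------------------------------
A = [
    ("cola", "cola drinks", "5", "4.2", "soda", 330, 18, 0.55, 1.0, 0.65),
    ("orange_soda", "orange soft drink", "5", "4.2", "soda", 330, 8, 0.65,
     1.0, 0.65),
    ("lemon_soda", "lemon soft drink", "5", "4.2", "soda", 330, 6, 0.70, 1.0,
     0.65),
    ("juice_packaged", "fruit juice, packaged", "4", "4.1", "juice_pack",
     200, 16, 0.50, 0.9, 0.50),
    ("milkshake", "milkshake", "5", "4.2", "dairy_dess", 200, 4, 0.70, 0.9,
     0.60),
    ("cheese_wedges", "cheese wedges, soft", "5", "4.2", "freshcheese", 25, 5,
     0.45, 0.8, 0.45),
    ("custard", "custard", "5", "4.2", "dairy_dess", 130, 9, 0.45, 0.8, 0.55),
    ("ice_cream", "ice cream", "5", "4.2", "dairy_dess", 100, 7, 0.45, 0.8,
     0.50),
    ("cookies_maria", "biscuits, plain (maria)", "4", "4.1", "cookie", 30, 9,
     0.35, 0.8, 0.50),
    ("cookies_chocolate", "biscuits, chocolate", "5", "4.2", "cookie", 30, 4,
     0.55, 0.9, 0.60),
    ("croissant", "croissant", "5", "4.2", "pastry", 60, 5, 0.50, 0.8, 0.55),
    ("donut", "doughnut", "5", "4.2", "pastry", 50, 3, 0.60, 0.9, 0.60),
    ("muffin", "muffin (magdalena)", "4", "4.1", "pastry", 40, 6, 0.45, 0.8,
     0.55),
    ("sponge_cake", "sponge cake", "4", "4.1", "pastry", 50, 4, 0.55, 0.9,
     0.55),
    ("chocolate_bar", "chocolate", "5", "4.2", "chocolate", 20, 4, 0.45, 0.9,
     0.50),
    ("cocoa_powder", "cocoa powder, sweetened", "5", "4.2", "cocoa_sweet", 12,
     2, 0.65, 0.9, 0.45),
    ("candies", "candies and sweets", "5", "4.2", "candy", 10, 1.5, 0.70, 0.9,
     0.55),
    ("nougat", "nougat (turron)", "4", "4.1", "turron", 30, 2, 0.60, 0.9,
     0.45),
    ("jam", "jam", "4", "4.1", "jam", 20, 4, 0.50, 0.8, 0.35),
    ("breakfast_cereals", "breakfast cereals", "5", "4.2", "cereal", 30, 5,
     0.55, 0.9, 0.50),
    ("sliced_bread", "sliced bread, packaged", "4", "4.1", "sliced_bread", 30,
     10, 0.55, 0.9, 0.55),
    ("frankfurter", "frankfurter sausage", "5", "4.2", "procmeat", 50, 6,
     0.50, 0.8, 0.60),
    ("mortadella", "mortadella and fiambres", "5", "4.2", "procmeat", 40, 5,
     0.50, 0.8, 0.60),
    ("cooked_ham", "ham, cooked", "4", "4.1", "procmeat", 40, 9, 0.35, 0.8,
     0.45),
    ("pate", "pate", "5", "4.2", "procmeat", 25, 2, 0.65, 0.9, 0.55),
    ("nuggets", "chicken nuggets", "5", "4.2", "readymeal", 80, 3, 0.65, 0.9,
     0.60),
    ("pizza", "pizza", "5", "4.2", "readymeal", 150, 8, 0.45, 0.8, 0.55),
    ("croquettes", "croquettes, frozen", "4", "4.1", "readymeal", 90, 5, 0.55,
     0.8, 0.55),
    ("french_fries", "french fries, frozen", "4", "4.1", "fries", 100, 7,
     0.50, 0.8, 0.55),
    ("potato_chips", "potato chips", "5", "4.2", "chips", 30, 4, 0.50, 0.9,
     0.55),
    ("instant_soup", "instant soup", "5", "4.2", "soup_inst", 200, 4, 0.70,
     0.9, 0.50),
    ("ketchup", "ketchup", "5", "4.2", "ketchup", 12, 1.5, 0.65, 0.9, 0.55),
    ("mayonnaise", "mayonnaise, industrial", "4", "4.1", "mayo", 15, 3, 0.50,
     0.8, 0.45),
    ("margarine", "margarine", "4", "4.1", "margarine", 12, 2, 0.60, 0.9,
     0.45),
    ("yogurt_sweetened", "yogurt, sweetened or flavored", "4", "4.1",
     "dairy_dess", 125, 18, 0.40, 0.9, 0.50),
    ("flan", "flan, packaged", "4", "4.1", "dairy_dess", 110, 6, 0.50, 0.8,
     0.50),
    ("whisky", "spirits (whisky, gin, rum)", "4", "4.2", "spirits", 45, 3,
     0.70, 1.0, 0.40),
]
industrial = {"milkshake", "cheese_wedges", "custard", "ice_cream"}
for item_id, label, ific, unc, tmpl, portion, mean, p0, sigma, loading in A:
    note = "assumed industrially produced" if item_id in industrial else ""
    add(item_id, label, "4", "3", ific, unc, note, tmpl, portion, mean, p0,
        sigma, loading)

# ---- unallocated record (1) ------------------------------------------------
add("mineral_water", "mineral water", "", "", "", "",
    "not allocated to a processing group", "water", 250, 400, 0.30, 0.8,
    0.0)

# ---- FFQ items outside the taxonomy (7; 143-item questionnaire) ------------
EXTRA = [
    ("tap_water", "tap water", "water", 250, 450, 0.25, 0.8, 0.0),
    ("herbal_infusions", "tea and herbal infusions", "infusion", 200, 55,
     0.50, 1.0, -0.10),
    ("saccharin", "non-caloric sweetener", "supplement", 1, 0.2, 0.75, 0.9,
     0.10),
    ("table_salt", "table salt, added", "supplement", 2, 3, 0.10, 0.6, 0.10),
    ("vitamin_supplement", "vitamin supplements", "supplement", 2, 0.3, 0.80,
     0.9, -0.05),
    ("protein_supplement", "protein supplements", "supplement", 10, 0.2, 0.92,
     0.9, 0.0),
    ("royal_jelly", "royal jelly", "supplement", 2, 0.1, 0.93, 0.9, -0.05),
]


# calibration: per-item mean g/day overrides, then a global scale so the
# implied mean energy lands near the cohort's (~2350 kcal/day) while the
# per-system UPF shares stay fixed (scaling is share-invariant).
MEAN_OVERRIDE = {
    # ultra-processed budget trimmed toward a 7.9% NOVA share
    "cola": 14, "orange_soda": 6, "lemon_soda": 5, "juice_packaged": 13,
    "milkshake": 3, "cheese_wedges": 4, "custard": 8, "ice_cream": 6,
    "cookies_maria": 8, "croissant": 4, "muffin": 5, "mortadella": 4,
    "cooked_ham": 8, "frankfurter": 5, "pizza": 7, "french_fries": 6,
    "sliced_bread": 9, "instant_soup": 3, "yogurt_sweetened": 15, "flan": 5,
    # dairy divergence block trimmed toward IFIC 20% / UNC 19.7%
    "milk_whole": 80, "milk_semi": 105, "milk_skim": 46, "yogurt_natural": 48,
    # IARC-only processed block trimmed toward 45.9%
    "beer": 72, "wine_red": 60, "bread_white": 100, "coffee": 82,
    # base enlarged so the non-UPF denominator matches
    "orange": 72, "apple": 56, "melon": 38, "watermelon": 38, "pear": 38,
    "mandarin": 32, "tomato_raw": 65, "banana": 34, "peach": 26, "green_beans": 35, "onion": 35,
    "zucchini": 28, "chicken": 62, "hake": 44, "potato_boiled": 74,
    "rice": 54, "pasta": 48, "eggs": 35, "carrot_cooked": 30,
}
SCALE = 0.80


def apply_calibration():
    global ITEMS, EXTRA
    ITEMS = [
        r[:9] + (MEAN_OVERRIDE.get(r[0], r[9]) * SCALE,) + r[10:]
        for r in ITEMS
    ]
    EXTRA = [e[:4] + (e[4] * SCALE,) + e[5:] for e in EXTRA]


def energy(tmpl):
    p, f, *_rest = T[tmpl][0:2]
    carb = T[tmpl][5]
    alc = T[tmpl][11]
    return 4.0 * (p + carb) + 9.0 * f + 7.0 * alc


def main():
    apply_calibration()
    assert len(ITEMS) == 136, len(ITEMS)
    ids = [r[0] for r in ITEMS]
    assert len(set(ids)) == 136
    counts = {
        "NOVA": sum(1 for r in ITEMS if r[2] == "4"),
        "IARC": sum(1 for r in ITEMS if r[3] == "3"),
        "IFIC": sum(1 for r in ITEMS if r[4] in ("4", "5")),
        "UNC": sum(1 for r in ITEMS if r[5] in ("4.1", "4.2")),
    }
    alloc = sum(1 for r in ITEMS if r[2] != "")
    print("allocated:", alloc, "counts:", counts)
    assert alloc == 135
    assert counts == {"NOVA": 37, "IARC": 82, "IFIC": 42, "UNC": 42}, counts
    # NOVA UPF subset of IARC UPF
    for r in ITEMS:
        if r[2] == "4":
            assert r[3] == "3", r[0]

    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "taxonomy_synthetic.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["item_id", "label", "nova", "iarc", "ific", "unc", "note"])
        for r in ITEMS:
            w.writerow(r[:7])

    comp_rows, par_rows = [], []
    for r in ITEMS:
        item_id, tmpl = r[0], r[7]
        comp_rows.append((item_id, tmpl))
        par_rows.append((item_id,) + tuple(r[8:13]))
    for item_id, label, tmpl, portion, mean, p0, sigma, loading in EXTRA:
        comp_rows.append((item_id, tmpl))
        par_rows.append((item_id, portion, mean, p0, sigma, loading))

    with open(OUT / "composition_synthetic.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["item_id", "energy_kcal", "protein_g", "fat_g", "sfa_g",
                    "mufa_g", "pufa_g", "carb_g", "fiber_g", "sugars_g",
                    "sodium_mg", "omega3_g", "gl"])
        for item_id, tmpl in comp_rows:
            p, f, sfa, mufa, pufa, c, fib, sug, na, o3, gi, alc = T[tmpl]
            gl = round(gi * c / 100.0, 3)
            w.writerow([item_id, round(energy(tmpl), 2), p, f, sfa, mufa,
                        pufa, c, fib, sug, na, o3, gl])

    with open(OUT / "item_parameters_synthetic.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["item_id", "portion_g", "mean_g_per_day", "zero_prob",
                    "sigma", "loading"])
        for row in par_rows:
            w.writerow(row)

    # calibration diagnostics: expected shares over *classified* grams
    classified = [r for r in ITEMS if r[2] != ""]
    total = sum(r[9] for r in classified)
    for sysname, col, upf in [("NOVA", 2, {"4"}), ("IARC", 3, {"3"}),
                              ("IFIC", 4, {"4", "5"}),
                              ("UNC", 5, {"4.1", "4.2"})]:
        s = sum(r[9] for r in classified if r[col] in upf)
        print(f"{sysname}: expected mean UPF share {100 * s / total:.1f}% "
              f"({s:.0f} g of {total:.0f} g)")
    kcal = sum(r[9] * energy(r[7]) / 100 for r in ITEMS)
    kcal += sum(e[4] * energy(e[2]) / 100 for e in EXTRA)
    print(f"expected energy {kcal:.0f} kcal/day")


if __name__ == "__main__":
    main()
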