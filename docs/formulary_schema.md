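# Formulary registry schema

The registry maps each Kampo extract product to its crude-drug composition.
It is a data file (CSV or JSON), never a constant, because compositions
vary by manufacturer.

## CSV form

Header columns:

| column | meaning |
| --- | --- |
| `product_name` | unique product name (duplicates are rejected) |
| `full_daily_dose_g` | grams of granule product in one full daily dose (> 0) |
| one column per crude drug | grams of that crude drug contained in one full daily dose; empty = not contained; values must be > 0 when present |

The crude-drug columns `SR`, `BR` and `PT` (Scutellariae radix, Bupleuri
radix, Pinelliae tuber) drive the exposure-group classification; any other
crude-drug columns are carried along but not analyzed.

Example row: a product taken at exactly its `full_daily_dose_g` delivers
each crude column's grams per day; at half that dose, half the grams.

## JSON form

A list of objects:

```json
[{"product_name": "Shosaikoto",
  "full_daily_dose_g": 7.5,
  "crude_content": {"SR": 3.0, "BR": 7.0, "PT": 5.0}}]
```

## The packaged example registry

`src/kampovig/data/formulary_example.csv` ships for tests and the analysis
scripts. Its compositions are **synthetic placeholders**: SR/BR/PT
membership is correct for every product named in the analyses (so group
classification is faithful), and magnitudes are plausible daily-decoction
grams, but only Shosaikoto's SR : BR : PT ratio (1.5 : 3.5 : 2.5) is
anchored to a published composition. The published ingredient list for
Shosaikoto names seven crude drugs against six proportion numbers; the
registry follows the standard recipe (jujube and ginseng sharing the
1.5-part entries). Replace this file with a manufacturer-accurate registry
for any real analysis.
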