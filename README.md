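# implant-access

Readiness, referral-network, and geographic-access analysis for
contraceptive implant **removal** services.

Subdermal implants are among the most used contraceptive methods in West
Africa, and every insertion eventually requires a surgical removal — usually
routine ("regular"), occasionally difficult (deeply embedded or
non-palpable, needing ultrasound localisation and specialised instruments).
Program managers need to know which facilities can actually manage which
cases, whether referral pathways send difficult cases to facilities that can
handle them, and how long clients must travel to reach a ready facility.
This package implements that three-part audit as a tested, reusable
pipeline for facility-survey and geographic data:

1. **Readiness** (`implant_access.readiness`) — SARA-style conjunctive
   classification of each facility into `NOT_READY` / `REGULAR` /
   `DIFFICULT` from three components (general service readiness, human
   resources, observed minimum equipment), driven by a declarative,
   swappable criteria table; district summary tables with whole-percent
   rounding.
2. **Referral** (`implant_access.referral`) — referral networks built from
   each facility's stated destination, facility roles
   (referring/receiving/standalone), and a *rationality* audit: are the
   facilities where cases terminate ready for them?
3. **Geographic access** (`implant_access.geoaccess`) — one-way travel time
   to the nearest ready facility. Urban model: road-network shortest paths
   with `minutes = wait + 60·km/speed` (defaults 50 min wait, 10 kph),
   extended to whole neighborhoods via Thiessen polygons. Rural model:
   walk-then-ride raster cost surface accumulated by multi-source Dijkstra
   on the 8-connected grid (step cost `d·(t_a+t_b)/2`). Either model feeds
   an hourly-band population overlay (bands `[60k, 60(k+1))`, `3+` cap).

A deterministic study fixture and seeded synthetic generators
(`implant_access.synthetic`) make the whole pipeline testable without any
real geodata.

## Worked example

```python
from implant_access import (
    build_paper_fixture, summarize_readiness, build_networks,
    assess_rationality, classify_all,
)

records = build_paper_fixture()          # 40 facilities, 2 districts
summary = summarize_readiness(records)   # assessed facilities only (39)
print(summary.table.loc[["Regular removals", "Difficult removals",
                         "Minimum equipment (regular)"]])
```

```
                             DAKAR_CENTRE  KOLDA  Total
Component
Regular removals                       77     69     72
Difficult removals                     15      4      8
Minimum equipment (regular)            77     81     79
```

72% of assessed facilities meet every condition for regular removals but
only 8% for difficult ones, and the binding constraint is equipment (79%
complete for regular removals). Joining the referral networks:

```python
build = build_networks(records)
print(sorted(n.size for n in build.networks))     # [4, 7, 20]
report = assess_rationality(build, records, classify_all(records))
print(report.to_series())
```

```
Referring facilities                28
Receiving facilities                 3
Standalone facilities                9
Assessed receiving-or-standalone    11
...ready for regular removals        7
...ready for difficult removals      1
dtype: int64
```

Of the 11 assessed facilities where cases terminate, seven are ready for
regular removals and only one for difficult removals — the referral system
routes difficult cases to facilities that cannot manage them.

For travel-time modeling, generate a synthetic geography and run the rural
model from the shell:

```sh
implant-access fixture --out fx
implant-access simulate --kind rural --seed 9 --out sim
implant-access access --facilities fx/facilities.csv --model rural \
    --surface sim/surface.asc --roads-raster sim/roads.asc \
    --population sim/population.asc --out out
cat out/access_table.csv
```

which writes the hourly-band access table (population counts and shares of
women of reproductive age per one-way travel-time band, summing to 100.0)
plus the accumulated travel-time raster. `implant-access readiness`,
`referral`, `simulate --kind urban|survey`, and `report` cover the rest of
the pipeline; see `docs/methods.md` for the models, defaults, and
limitations, and `docs/criteria_default.json` for the shipped readiness
criteria.

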