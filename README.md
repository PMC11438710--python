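# riparify

River-network restoration prioritization and riparian landscape analysis.

Lowland river systems — channelized, fragmented by migration barriers, and
squeezed by farmland and urban growth — are restored piecemeal, often one
administrative unit at a time. `riparify` implements a transferable,
vector-native priority model that scores every channel sequence of a river
network on four criteria and ranks the whole system at once, together with
the class-level landscape metrics and riparian-buffer composition analysis
used to quantify how the surrounding land cover has changed. It is aimed at
conservation planners and landscape ecologists who have a segmented,
attributed river layer and a polygonal land-cover map in a planar metric
CRS.

## The priority model

Each river sequence *i* receives 0–2 points on four criteria:

| criterion | levels → points |
|---|---|
| barrier (fish-migration obstacle) | yes → 2, no → 0 |
| ecomorphological condition (EC) | natural → 0, semi-natural → 1, artificial → 2 |
| national priority species (NPS) | present → 0, absent → 1, absent but adjacent to a flagged sequence → 2 |
| high diversity of aquatic species (HDAS) | present → 0, absent → 1, absent but adjacent → 2 |

"Adjacent" means within 500 m measured **along the network** (shortest path
over the node graph, segment lengths as edge weights) — the rationale is
species migration, which follows the channel. The weighted score is

    S_i = 4 · Σ_c w_c · p_ic / Σ_c w_c      ∈ [0, 8]

so that the default equal weights (w = 0.25 each) make S the raw point sum.
S is binned into `very_low` [0,1], `low` (1,3], `moderate` (3,5], `high`
(5,7], `very_high` (7,8] (only the extremes are fixed by the model; the
middle edges are configurable). Restored sequences are reported as their
own `already_restored` category, and any sequence with an unknown criterion
is reported as `unknown` rather than guessed.

The landscape engine computes class-level vector metrics — number of
patches (NP), mean patch size (MPS, ha), edge density (ED, m/ha), mean
nearest-neighbor distance (MNND, m) and mean shape index
(MSI = P / 2√(πA), 1 for a circle) — plus epoch-to-epoch area change
tables, and the land-cover composition of 40 m riparian buffers per
priority category.

## Worked example

`make_worked_fixture()` builds a six-sequence chain that exercises every
scoring branch:

```python
import riparify as rp

net, _ = rp.make_worked_fixture()
scored = rp.score_network(net)
for s in sorted(scored, key=lambda s: s.segment_id):
    print(f"{s.segment_id:8s} points={s.points} score={s.score} {s.category}")
```

```
done     points=(None, None, None, None) score=None already_restored
far      points=(0, 1, 1, 1) score=3.0 low
hot      points=(0, 0, 0, 0) score=0.0 very_low
near     points=(2, 1, 2, 2) score=7.0 high
nodata   points=(2, None, 1, 1) score=None unknown
worst    points=(2, 2, 2, 2) score=8.0 very_high
```

`worst` contains a barrier, has an artificial bed, and lacks both species
flags while sharing a node with the flagged `hot` — every criterion maxes
out, giving 8 and `very_high`. `near` is 400 m along the network from
`hot`, so both adjacency bonuses still apply (score 7); `far` is 600 m
away, beyond the 500 m migration rule, so its species criteria fall back
to 1 point each (score 3). `nodata` has unknown EC and is not scored;
`done` is already restored.

The same pipeline from the shell:

```sh
riparify simulate network --seed 1 --n 200 --out net.geojson
riparify score --network net.geojson --out scored.geojson --report report.csv
riparify report --scored scored.geojson --by-state --out by_state.csv
riparify simulate mosaic --seed 1 --out lc.geojson
riparify buffers --scored scored.geojson --landcover lc.geojson --width 40 --out composition.csv
```

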