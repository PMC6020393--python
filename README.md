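# popaccess

Population-weighted spatial accessibility of a population to point
destinations — bars and restaurants, clinics, grocery stores — measured from
the smallest census-style demand units and rolled up any geographic
hierarchy.

Public-health and geography analysts often summarize "access" as the count
of destinations inside an administrative boundary, which assumes equal
access for everyone in the container and ignores destinations just across
its edge. `popaccess` implements the gravity-model alternative: every demand
unit (a *block*, with a centroid and a population count) gets a choice set
of its *n* nearest destinations under three distance engines — straight-line
(great-circle) distance, street-network driving distance, and street-network
driving time — and from each choice set two complementary measures:

* the **spatial accessibility index** (gravity score)

  $$A_i = \sum_{j=1}^{n} \frac{w_j}{d_{ij}^{\beta}}$$

  with distance-decay exponent β (default 1), destination weights
  $w_j$ (default 1, i.e. all destinations treated equally), and $d_{ij}$ the
  distance from block *i* to its *j*-th nearest destination (miles, or
  minutes for the travel-time metric);

* the **population-weighted distance**

  $$PWD_i = \sum_{j=1}^{n} P_{ij}\, d_{ij}, \qquad
    P_{ij} = \frac{d_{ij}^{-\beta}}{\sum_{k=1}^{n} d_{ik}^{-\beta}}$$

  where $P_{ij}$ is the Huff-model probability that a resident of block *i*
  chooses destination *j* — nearer destinations are visited more often, but
  not exclusively. For β = 1 and unit weights, $PWD_i$ is the harmonic mean
  of the choice-set distances and $PWD_i \cdot A_i = n$ exactly.

Block values aggregate to tracts, counties, states or a whole region by
population weighting,

$$PWA_k = \frac{\sum_i Pop_i A_i}{Pop_k}, \qquad
  PWD_k = \frac{\sum_i Pop_i\, PWD_i}{Pop_k},$$

which nests exactly (block→county equals block→tract→county), so results do
not depend on the intermediate zoning. Counties are classified on the
six-class NCHS urban–rural scheme (large central metro … noncore) for
stratified summaries, and the six measures (3 engines × {PWA, PWD}) are
compared with Pearson correlations.

Because the licensed national inputs such analyses use (commercial
point-of-interest feeds, census block files, routable street data) cannot
be redistributed, the package ships a seeded synthetic-geography generator
— heavy-tailed block populations on an urban→rural county grid, outlets
clustered toward population, a speed-attributed street grid — that
reproduces the qualitative structure of real studies: a monotone
metro→noncore access gradient and strongly correlated measure families.

## Worked example

```python
import popaccess as pa

region = pa.generate_region(pa.RegionConfig(seed=1))   # 720 blocks, 200 outlets
res = pa.run_pipeline(region.blocks, region.outlets, region.nodes,
                      region.edges, region.nchs, mode=region.mode)
print(res.summaries["national"].round(3).to_string(index=False))
```

```
 area_id    level         metric     PWA   PWD    pop  n_blocks
national national drive_distance 130.729 0.837 495166       710
national national     drive_time 128.587 1.431 495166       710
national national      euclidean  18.204 0.792 495166       710
```

The 495,166 simulated residents live on average 0.84 network miles (1.43
driving minutes, 0.79 straight-line miles) from their 7 nearest outlets in
the Huff-weighted sense; PWA is the matching gravity index in reciprocal
metric units (1/minute, 1/mile). Stratifying county-level driving-distance
PWD by NCHS class shows the urban–rural gradient:

```python
s = res.stratified
pwd = s[(s.measure == "PWD") & (s.metric == "drive_distance")]
print(pwd[["nchs_class", "nchs_label", "count", "mean", "sd", "median"]]
      .round(2).to_string(index=False))
```

```
 nchs_class          nchs_label  count  mean   sd  median
          1 large central metro      4  0.37 0.10    0.36
          2  large fringe metro      4  0.70 0.47    0.60
          3        medium metro      4  1.34 0.25    1.32
          4         small metro      4  1.98 0.41    2.04
          5        micropolitan      4  2.29 0.28    2.26
          6             noncore      4  3.50 1.24    3.14
```

— residents of large central metro counties are roughly ten times closer to
outlets than noncore residents. `res.correlations` holds the 6×6 Pearson
matrix: the three PWA measures are strongly positively inter-correlated, as
are the three PWD measures, while PWA–PWD pairs correlate negatively
(higher gravity access ↔ shorter weighted distance).

The same workflow is available from a shell:

```sh
popaccess simulate --seed 1 --outdir region
popaccess all --blocks region/blocks.csv --outlets region/outlets.csv \
    --nodes region/nodes.csv --edges region/edges.csv --nchs region/nchs.csv \
    --mode planar --outdir out
```

which writes `block_metrics.csv`, per-level `summary_*.csv`,
`stratified_nchs.csv`, `correlations.csv` and a `run_log.json` with the
bookkeeping counts (blocks read, zero-population blocks dropped,
network-excluded blocks per metric).

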