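# pcaplanes

Strain prioritization for natural-product discovery from untargeted LC-MS
metabolomics of bacterial collections.

When a collection of related bacterial strains (typically actinomycetes) is
profiled by LC-MS, the resulting bucket table — strains × (RT, *m/z*)
features — easily holds 10⁵–10⁶ features, most of them media components,
common metabolites and noise-threshold signals shared across strains.
The chemistry worth isolating is the opposite: masses produced by exactly
one strain. `pcaplanes` finds them automatically:

1. **PCA** of the sum-normalized, Pareto-scaled table. Features common to
   all strains contribute nothing to variance and collapse to the center of
   every loadings plot; strain-specific chemistry drives specific
   components.
2. **Plane search**: for each strain, find the pair of principal components
   on which its score is farthest from every other strain's — the plane in
   which that strain "stands out". This is often a *high* plane (PC13 vs
   PC15, say, not PC1 vs PC2): low-abundance or poorly ionizing unique
   compounds carry little total variance.
3. **Unique-mass extraction**: filter the raw bucket table for features
   present in that strain only, and rank them by Euclidean loading distance
   in the strain's best plane.
4. **Dereplication** (optional): convert each unique *m/z* to a neutral
   monoisotopic mass under adduct rules ([M+H]⁺ by default) and match it
   against a compound-mass database within a ppm tolerance; masses with no
   hit are flagged as putatively novel.

The output is a short ranked list per strain (60 entries by default) in an
Excel workbook or CSV — a day's worth of inspection instead of a month's.

## Model

Let `X` be the n×p bucket table after replicate averaging, range filtering
(RT 2–14 min, *m/z* 150–1500 by default), row-sum normalization and Pareto
scaling `x'ᵢⱼ = (xᵢⱼ − x̄ⱼ)/√sⱼ`. The SVD `X = U S Pᵀ` gives scores
`T = U S` and orthonormal loadings `P`; component k explains `S²ₖ/(n−1)`
of the variance, and at most n−1 components survive centering.

For strain s and component k the separation gap is the nearest-neighbor
score distance `gₛₖ = min_{r≠s} |Tₛₖ − Tᵣₖ|`; the best plane pairs the two
components with the largest gaps. Feature f is *unique* to strain s when
`X_raw[s,f] > 0` and `X_raw[r,f] ≤ α·X_raw[s,f]` for all r≠s (α = 0 by
default, i.e. strictly exclusive presence), and is ranked by
`d_f = √(P²_f,i + P²_f,j)` in the selected plane (i, j).

## Worked example

Generate a synthetic 10-strain collection with 500 shared background
features and 3 planted unique metabolites per strain, then run the full
workflow with a one-entry compound database:

```python
from pcaplanes import (CompoundDB, SynthSpec, generate, run_workflow)

spec = SynthSpec(n_strains=10, n_background=500, n_unique_per_strain=3,
                 dropout_rate=0.0, seed=7)
ds = generate(spec)
known = sorted(ds.truth["S01"])[0]          # pretend one compound is known
db = CompoundDB(names=["examplamycin A"], masses=[known.mz - 1.007276])
res = run_workflow(ds.table, db=db)

rep = res.reports[0]
print(f"{rep.strain_id}: best plane PC{rep.plane[0]} vs PC{rep.plane[1]}")
for r in rep.records:
    print(r.rank, round(r.feature.rt, 2), round(r.feature.mz, 4),
          round(r.distance, 4), r.match_name, r.novel)
```

This prints (stage counts go to the log):

```
INFO features: 530 in, 530 after RT 2-14 min / m/z 150-1500 filter
INFO PCA: 10 strains, 9 retained components
INFO S01: plane PC9 vs PC8, 3 unique features (3 reported)
...
S01: best plane PC9 vs PC8
1 3.13 717.3275 0.5384 examplamycin A False
2 13.89 1267.232 0.5055 None True
3 3.64 1267.866 0.4165 None True
```

Strain S01 separates best in the PC9/PC8 plane; its three planted unique
masses are recovered exactly, ranked by how strongly they drive that
separation. The 717.3275 ion matched the database as the [M+H]⁺ of
examplamycin A (dereplicated — known compound), while the other two masses
have no database hit and are flagged novel: those are the isolation
candidates. All 500 background features are excluded — they sit at the
center of the loadings plane.

The same pipeline is available from the shell:

```sh
pcaplanes synth --n-strains 10 --n-background 500 --n-unique 3 \
    --dropout 0 --seed 7 --out-dir fixture/
pcaplanes run --input fixture/bucket_table.csv --dialect wide_csv \
    --format csv --out reports.csv
pcaplanes derep --db compounds.csv --mz 901.4205
pcaplanes overview --input fixture/bucket_table.csv --dialect wide_csv \
    --out gaps.csv     # per-strain gap matrix ("scores overview")
```

Real bucket tables export from ProfileAnalysis / MZmine / XCMS as
tab-delimited or CSV files (`--dialect vendor_txt|wide_csv|long_csv`); a
compound database is a CSV with `name, monoisotopic_mass[, formula]`
columns.

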