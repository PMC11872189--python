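# ethonet

Quantitative ethology of ethogram-coded behavioral sequences, built around
the analysis chain used to study chimpanzee termite fishing from
camera-trap video: technique mining, repertoire statistics, cross-community
similarity, and epistemic network analysis (ENA) of how behavioral elements
are combined.

## Who this is for

Behavioral ecologists and primatologists who code video into event
sequences — one row per behavioral element onset, elements mutually
exclusive in time, onsets on a quarter-second grid — and want to go from
those tables to individual repertoires, community comparisons, and
co-occurrence network models, with every step scriptable from Python.

## What it computes

**Technique mining.** A *technique* is a contiguous run of 2–7 behavioral
elements containing a probing element followed by an extraction element.
The miner enumerates every n-gram of each (subject, video) sequence, keeps
the functional ones, and counts per-subject usage (overlapping and nested
occurrences counted; a maximal-only convention is available).

**Repertoire statistics.** Bootstrap rarefaction curves (videos resampled
in random accumulation order) flag subjects whose element inventories have
saturated; Fisher's exact tests screen technique-usage differences between
subjects (raw and Benjamini–Hochberg adjusted p side by side); hierarchical
clustering of the globally max-normalized usage matrix visualizes
repertoire similarity.

**Sørensen similarity.** Between element repertoires A and B, stratified by
mound type:

    S(A, B) = 2·N_shared / (2·N_shared + N_only_A + N_only_B)

**Epistemic network analysis**, implemented from scratch. Per chimpanzee
(the unit), element-pair co-occurrences are accumulated over a moving
stanza window of w lines within each conversation (one subject's video):
a pair connects on a line when one element is present there and the other
anywhere in the window, at most once per line. The upper-triangle vectors
are normalized to the unit sphere, mean-centered, and projected by SVD onto
SVD1/SVD2; element nodes are co-registered by least squares so each unit's
edge-weighted network centroid approximates its projected point (the
point–centroid correlation is the goodness of fit). Communities are
compared per axis with Mann–Whitney U tests and rank-biserial effect sizes
r = 1 − 2U/(n₁n₂), and drawn with group means and 95% CI boxes.

**Synthetic corpora.** Because coded field corpora are rarely
redistributable, `ethonet.synthetic` generates seeded camera-trap corpora
(20 s/60 s clips, quarter-second onsets) from a first-order Markov chain
with a probe→extract grammar, planted community pair-affinities, and
mother–offspring propensity mixing — with the ground truth returned for
recovery testing.

## Worked example

```python
import ethonet as en

cfg = en.SyntheticConfig(seed=5)
_, matrix, truth = en.generate_corpus(cfg)

vectors = en.accumulate_adjacency(matrix, en.StanzaConfig(window=4))
space = en.position_nodes(en.ena_project(vectors))
print(space.variance_explained)
for axis in ("SVD1", "SVD2"):
    c = en.compare_groups(space, "community_1", "community_2", axis)
    print(axis, c.u, round(c.p_value, 4), round(c.effect_size, 2))
```

prints (examples/04_ena_model.py):

```
variance explained: SVD1 42.2%, SVD2 13.8%
SVD1: U = 62.0, p = 0.0006, r = -0.94 (n = 8, 8)
SVD2: U = 31.0, p = 0.9591, r = +0.03 (n = 8, 8)
community_1: strongest connection ('Sit', 'Shake side') (planted habit pair was ('Shake side', 'Sit'))
community_2: strongest connection ('Lean', 'Oscillate') (planted habit pair was ('Oscillate', 'Lean'))
```

The two synthetic communities were generated with different planted
element-pair habits; the model separates them almost completely along SVD1
(|r| close to 1), leaves SVD2 uninformative, and each community's mean
network is dominated by exactly the pair that was planted for it. The
`examples/` directory holds one short script per capability (mining,
rarefaction + clustering, Sørensen profiles, ENA, full pipeline).

A thin CLI wraps the same functions:

```
ethonet simulate --seed 42 --out-prefix sim
ethonet widen sim_events.csv --bin 5 -o wide.csv
ethonet ena wide.csv --window 4
ethonet run --config analysis.yaml
```

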