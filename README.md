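# sectornet

Sociometric analysis of intersectoral health-coalition networks.

Community coalitions that unite community-based organizations, researchers,
policymakers, providers, philanthropic and public-sector agencies are a
standard instrument against health disparities, and evaluators increasingly
ask a network question about them: did the initiative actually create
cross-sector relationships, and do members with more (and more reciprocated)
intersectoral connections deliver more — community activities, grants and
publications, policy engagement?  `sectornet` implements the full analysis
such an evaluation needs, for the fixed-roster, directed, binary
("member *i* reported connecting with member *j*") survey design these
studies use:

* **Whole-network structure** — density `Δ = L / n(n−1)`, dyad- and
  arc-based reciprocity, Freeman out-degree centralization
  `C = Σᵢ(c_max − cᵢ) / (n−1)²`, raw Freeman betweenness on directed
  geodesics, degree profiles (out, in, and union degree).
* **Sector-block statistics** — within/between-sector tie densities on the
  union-symmetrized network (a tie counts whichever member reported it) and
  directional reciprocation shares (the share reported by sector G toward
  sector H that H returned — legitimately asymmetric), with two-wave
  "Δ (early–late)" change tables.
* **Outcome indices** — three unweighted binary-item sums per member:
  community activities (0–4), grants/publications (0–3), policy engagement
  (0–2).
* **Permutation regression** — node-level OLS
  `index ~ focal + city + tenure + sector` where inference comes from
  re-ordering the outcome vector across members (default 10,000
  Y-permutations; Freedman–Lane residual permutation optional; exhaustive
  enumeration for tiny n), because members of one network are not
  independent observations.  A collinearity screen (|r| > 0.70) refuses
  model specifications whose predictors cannot be separated.
* **Synthetic data** — a seeded generator producing rosters, nested two-wave
  sociomatrices and outcome items with known ground truth, calibrated so the
  default coalition grows from ~16% to ~35% density and ~19% to ~54%
  reciprocity between waves.

## Worked example

```python
from sectornet import GeneratorConfig, generate_dataset, summarize

ds = generate_dataset(GeneratorConfig(), seed=7)
for wave in (ds.waves.inception, ds.waves.year4):
    s = summarize(wave)
    print(f"{s.wave:>9}: density {s.density:.0%}  "
          f"dyad reciprocity {s.reciprocity:.0%}")
```

prints

```
inception: density 17%  dyad reciprocity 17%
    year4: density 36%  dyad reciprocity 55%
```

— the share of possible directed ties reported, and the share of connected
pairs both members confirmed, at each wave of this seeded coalition.
Regressing the community-activities index on intersectoral out-degree with
permutation inference (`examples/03_permutation_regression.py`) gives

```
community_activities   beta = +0.250  p_perm = 0.0001  R2 = 0.54
```

i.e. each additional cross-sector tie predicts a quarter-point higher index,
holding city, tenure and sector fixed, with a two-sided permutation p-value
from 10,000 re-orderings.  The `examples/` directory holds one short script
per capability; the `sectornet` CLI (`simulate`, `analyze`, `layout`) drives
the same pipeline from a shell and writes a report directory whose
`report.json` is byte-identical across reruns with the same config and seed.

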