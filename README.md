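# metabodnm

Paired plasma-metabolomics analysis with dynamic-network-marker detection.

`metabodnm` re-analyses a classic short-term-fasting study design: the same
individuals are sampled in a post-absorptive (baseline) state and again
after a 24-h fast, and an untargeted metabolome (hundreds of metabolite
intensities per sample) is profiled for each. The package is aimed at
physiologists and systems biologists who want, from a single intensity
table and sample sheet:

1. **Differential metabolite expression** respecting the paired design,
   with empirical-Bayes variance moderation and Benjamini–Hochberg control;
2. **Multilevel PLS-DA** (supervised discrimination on within-subject
   deviations) and a **higher-order SVD** of the metabolite × individual ×
   condition tensor;
3. **Per-condition association networks** from Gaussian-copula mutual
   information with ARACNE/DPI pruning of indirect edges;
4. **Topological modules** (leading-eigenvector modularity), eigenvector
   centralities and cross-condition module matching;
5. **Dynamic-network-marker (DNM) identification**: the fasted-state module
   whose members jointly show high centrality, the largest paired
   centrality gain, elevated between-individual variability and a large
   modularity contribution — the signature of a network re-organising
   ahead of a physiological state shift.

A synthetic-data generator with planted ground truth (modules, fold
changes, a DNM module) makes every stage testable end to end.

## The models in brief

**Moderated paired t.** For metabolite $g$ with within-subject log2
differences $d_{gi}$ ($i = 1..n$ individuals), sample mean
$\mathrm{LFC}_g$ and variance $s_g^2$ on $d_g = n-1$ df, a scaled
inverse-$\chi^2$ prior $s^2 \sim s_0^2 d_0/\chi^2_{d_0}$ is fitted across
metabolites by moments of $\log s_g^2$, giving

$$\tilde s_g^2 = \frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g},\qquad
  t_g = \frac{\mathrm{LFC}_g}{\sqrt{\tilde s_g^2/n}} \sim t_{d_0+d_g}.$$

**Networks.** Within one condition, the mutual information between two
metabolites across individuals is estimated as
$\hat I = -\tfrac12\ln(1-\hat r^2)$ with
$\hat r = 2\sin(\pi r_s/6)$ from the Spearman correlation $r_s$; an edge
$(i,j)$ is removed when some third metabolite $k$ satisfies
$I_{ij} < \min(I_{ik}, I_{jk})$ (the data-processing inequality).
Modules maximise modularity
$Q = \tfrac1{2m}\sum_{ij}(A_{ij} - k_ik_j/2m)\,\delta(c_i,c_j)$ via
recursive leading-eigenvector bisection; centralities are the Perron
eigenvector of the weighted adjacency, max-normalised.

**DNM ranking.** Every non-singleton fasted module is ranked on mean
centrality, mean paired centrality change, mean fasted between-individual
CV and its contribution to $Q$; the best mean rank is the candidate. A DNM
is declared only when the module factor explains fasted CV (GLM
$F$-test, $p<0.05$) *and* does so much more strongly than at baseline
($F_\text{fasted} > 3F_\text{post}$).

## Worked example

```sh
metabodnm simulate --seed 1 --out demo_data/
metabodnm run --data demo_data/ --out demo_run/
metabodnm dnm-report demo_run/
```

Equivalently, the numbered scripts under `analysis/` run the same stages
with a planted strong-effect dataset and narrate what they find. On that
dataset (seed 1) they print:

```
catalogue: 322 metabolites, 219 identified, 103 unidentified
planted: 151 differentially expressed metabolites, DNM module 14 with 32 members
150 of 322 metabolites significant at BH-adjusted P < 0.05
PLS-DA components explain 70.7% and 19.4% of the X variance
95% group ellipses overlap: False
post: 884 edges (density 0.017), 18 modules, Q = 0.568
selected DNM module: 2 (size 30), detected: True
planted-module recovery: ... DNM hit: True
```

Reading this: 150 of the 322 simulated metabolites change significantly
after "fasting"; the two conditions separate completely in the PLS-DA score
plane (non-overlapping 95% ellipses); the baseline network splits into 18
modules at modularity Q ≈ 0.57; and the module selected by the four-way DNM
ranking is the planted one (30 of its 32 members recovered — a "hit" means
the selected module has the maximal Jaccard overlap with the planted
module).

## Layout

- `src/metabodnm/` — the library (each stage importable on its own)
- `analysis/` — numbered narrative drivers, 01 simulate … 05 DNM
- `tests/` — pytest suite incl. Monte-Carlo acceptance checks
- `docs/methods.md` — models, assumptions, parameter choices, limitations
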