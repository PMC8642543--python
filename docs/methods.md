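# Methods

This note documents the models, defaults and numerical choices behind
`mitonorm`, in the order the pipeline runs them.

## Synthetic cohort model

The generator produces the data-generating process the analysis assumes,
with full ground truth.

**Signal.** Protein $g$ in sample $s=(p,t)$ (participant $p$, timepoint
$t$) has pre-noise intensity

$$x_{gs} = \beta_g \cdot (c_t\,e_s)^{m_g}\cdot 2^{\,\delta_{gt} + u_{gp}}$$

* $\beta_g$ — baseline intensity, $\log_2\beta_g \sim N(25,\,2.5^2)$
  i.i.d. per feature. A typical LFQ dynamic range (~$10^5$–$10^{10}$
  arbitrary intensity units); configurable.
* $m_g \in \{0,1\}$ — mitochondrial flag; a fraction `mito_fraction`
  (default 0.40) of the 1500 features is mitochondrial, matching the
  reported ~41% mitochondrial identification share in muscle
  mitochondrial isolates.
* $c_t$ — the global content multiplier. By default it is **calibrated at
  generation time**: with $R$ the realised baseline ratio of summed
  mitochondrial to non-mitochondrial intensity, the enrichment satisfies
  $\mathrm{MPE}_t = 100\,R c_t/(R c_t + 1)$, so
  $c_t = \mathrm{odds}(\mathrm{MPE}^{\text{target}}_t)/R$ hits the target
  trajectory (default 24.5/31.5/39.3/34.5%) exactly in the noise-free
  limit. An explicit multiplier vector can be supplied instead.
* $e_s$ — per-sample enrichment-efficiency jitter,
  $\log_2 e_s\sim N(0, 0.10^2)$. Isolate purity varies between
  preparations; the magnitude is a realism choice, not a literature value.
* $\delta_{gt}$ — true per-feature log2 deviation from the content trend,
  organised in effect classes; the first timepoint is re-anchored to 0.
  All effect classes are drawn from the mitochondrial pool; remaining
  mitochondrial features are the "stoichiometric" class ($\delta=0$).
  Two helpers ship: `two_group_effects` (30 up / 30 down at
  $|\delta|=1$) and `six_cluster_effects`, six classes whose mean-centred
  profiles form an orthogonal $\pm$ design (late up/down, mid peak/dip,
  alternating up/down; amplitude 2) so that the classes are separable by
  clustering, as classes defined *by* clustering are.
* $u_{gp}$ — participant-by-feature effect, $N(0, 0.10^2)$ on log2,
  constant over timepoints. This induces within-participant correlation
  and makes the blocking factor meaningful. A per-participant *column*
  scalar would be annihilated by the closure below and was deliberately
  not used.

**Noise.** $y = x\,e^{\varepsilon_m} + |\varepsilon_a|$ with
$\varepsilon_m \sim N(0, \text{cv}^2)$ (default cv = 0.2, natural-log
scale) and $\varepsilon_a \sim N(0, \text{sd}_a^2)$ folded at zero
(default $2\times10^4$ intensity units). Multiplicative plus additive
noise produces the mean–variance dependence the VSN step is designed for.

**Closure.** Each sample column is rescaled to a constant total (the
baseline summed mass): equal protein loaded per LC-MS run. This is the
mechanism that converts a content change into an apparent per-protein
shift. Closure cancels in the MPE ratio, so the calibration above is
unaffected.

**Missingness.** Each value is masked with probability
$\sigma\!\big((\tau_s - \log_2 y)/\gamma\big) + \text{mcar}$, capped at 1.
Defaults: $\tau_s$ at the 5th percentile of the sample's log2 intensities,
$\gamma = 0.4$ log2 units, MCAR floor $10^{-3}$, giving ~6% overall
missingness concentrated at low intensity. These were fixed by a pilot
power analysis: left-censored imputation necessarily adds large variance
to any feature with imputed entries (see *Imputation* below), so the
missingness level controls how many features pay that penalty. The
defaults describe high-quality LFQ with match-between-runs on abundant
organelle proteins; heavier censoring is available and simply costs
power.

**Lipidome.** 300 species, ~10% cardiolipins; CL species carry
$c_t\,e'_s$, other classes are flat; multiplicative noise cv = 0.15; no
closure (targeted concentrations against internal standards).

**Reproducibility.** Each output matrix has its own RNG stream derived
from the config seed plus a fixed offset, so components can be
regenerated independently and byte-identically.

**What the generator does not emulate.** Peptide-level identification,
match-between-runs correlation structure, ratio compression, batch/run
order drift, annotation errors, and correlated (complex-stoichiometric)
noise between subunits. Passing recovery tests therefore demonstrates the
statistical mechanics of the chain, not robustness to those real-data
phenomena.

## MPE

Computed on the **full** matrix before any filtering, from **raw**
intensity columns (not LFQ), with missing values as 0 in both sums —
"Known Mitochondrial" annotation only, by default. The closed form above
is tested to 1e-9 on noise-free output.

## Valid-value filter

Features observed in at least 70% of samples are kept; the boundary is
inclusive (a feature at exactly 70% stays, since removal applies to
features *below* the threshold). The count comparison uses an absolute
guard of 1e-9 to avoid binary-representation artefacts at the boundary.

## Variance-stabilising transform

Per sample, $h_s(x) = \mathrm{glog}_2(a_s + b_s x)$ with
$\mathrm{glog}_2(z) = \log_2(z+\sqrt{z^2+1}) - 1$; the $-1$ makes
$\mathrm{glog}_2(z)\to\log_2 z$ for large $z$. Parameters are fitted by
maximising the profile likelihood of the model
$h_s(x_{gs}) \sim N(\mu_g, \sigma^2)$: row means and $\sigma^2$ are
profiled out analytically; the transform's Jacobian term keeps $b_s$ from
collapsing; optimisation is joint over all $(a_s, \log b_s)$ with an
analytic gradient (L-BFGS-B, `ftol` 1e-15). Robustness is
least-trimmed-squares: after each fit, features above the 0.9 quantile of
residual sums are excluded and the fit repeats until the trimmed set
stabilises (this is the `iterations` diagnostic; non-stabilisation after
20 rounds raises with diagnostics attached). Missing entries are ignored
during fitting and remain missing.

The absolute scale is anchored by subtracting the median of
$\log_2 b_s$, so the cohort-median sample's transform matches $\log_2$
asymptotically and differences are interpretable as log2 fold changes.
Initialisation: $a_s = 0$, $b_s = 1/\text{median}(x_s)$.

Whether the transform is fitted on the mitochondrial subset (default,
following the published order: subset, then normalise) or on all retained
features with subsetting afterwards is a config switch
(`vsn_scope="mito"|"all"`); the source description is ambiguous on this
point and the package does not claim either is "the" published variant.

## Left-censored imputation

Per sample: the observed order statistic $y_{(i)}$ is assigned overall
quantile $p_i = (n_{\text{miss}} + i - 0.5)/n_{\text{total}}$ (all
missing mass assumed below it — left censoring); ordinary least squares
of $y_{(i)}$ on $\Phi^{-1}(p_i)$ over the uncensored quantile range
(default 0.25–1.0) gives the complete distribution's mean and sd; missing
entries are drawn from that normal truncated above at the sample's
observed minimum. Samples with fewer than 10 observed values raise.
Draws are deterministic for a fixed seed; one generator is shared across
samples in column order.

*Known limitation:* the draws come from the sample-wide distribution, not
the feature's own, so a feature with even one imputed entry gains a large
residual variance; and under *soft* (logistic) censoring some masked
values truly lay above the observed minimum, so truncating there biases
imputed values slightly low. On content-change-only cohorts this leaves a
residual mean shift of ~0.01–0.05 log2 between timepoints with unequal
censoring depth — an order of magnitude below the ~0.5 log2 artefact the
chain removes, and visible in the chain-invariant test.

## Moderated statistics

OLS per feature on intercept + timepoint + participant (fixed-effect
blocking; a switch drops the block). Contrast schemes: `phase`
(PN−BL, PH−PN, PR−PH; the default global test) and `vs-baseline`
(PN−BL, PH−BL, PR−BL). Empirical-Bayes moderation follows the
moment-matching recipe on $e_g = \log s_g^2 - \psi(d/2) + \log(d/2)$:
$\psi'(d_0/2) = \max(\mathrm{var}(e) - \psi'(d/2),\ \epsilon)$ solved by
Newton trigamma inversion, $s_0^2 = \exp(\bar e + \psi(d_0/2) -
\log(d_0/2))$; non-positive excess variance takes the $d_0 = \infty$
branch ($\tilde s^2 \equiv s_0^2$, normal/χ² reference distributions).
Moderated $t$ uses $d_0 + d$ df; the moderated $F$ is the quadratic form
in the contrast covariance divided by $r\,\tilde s^2$. The implementation
reproduces the limma reference to ~1e-10 on a frozen fixture
(tests/test_de.py); note that in the degenerate all-equal-variance case
the bias-corrected prior sits slightly above the common observed value —
this matches the reference implementation exactly.

BH adjustment is the step-up definition with missing p-values propagated
and excluded from $m$; it is order-equivariant and is cross-checked
against both a brute-force implementation and statsmodels.

## Permutation FDR

Welch $t$ (unequal variances, no SAM-style fudge constant) between two
timepoints, treated as unpaired by default — mirroring the published
choice on what is formally a paired design; a paired sign-flip mode is
provided. Relabelings are exhaustive when at most $20\,n_\text{perm}$
exist (e.g. all 20 at $n{=}3$ vs 3), otherwise $n_\text{perm}$ distinct
relabelings are sampled without replacement.
$\mathrm{FDR}(c) = \overline{\#\{|t_\text{null}|\ge c\}}/
\max(1, \#\{|t_\text{obs}|\ge c\})$, and the q-value is the minimum FDR
over thresholds at or below the feature's own $|t|$, clipped to $[0,1]$ —
monotone non-increasing in $|t|$ by construction. The two-tier call set
intersects $\{q < 0.05\}$ with the global moderated-F set
(proteins $\alpha=0.01$, lipids $\alpha=0.05$).

## Structure

Rows are z-scored with the sample-sd ($n-1$) convention; constant rows are
dropped with a warning. Clustering is scipy agglomerative linkage
(complete for proteins/lipids, average retained as a config value) on
Euclidean distances of z-scored rows; $k$ is a config value (default 6 —
the published cut count; no cut criterion is inferred). Exact distance
ties are resolved by scipy's deterministic agglomeration order; on
continuous z-scored data ties have probability zero, and row-permutation
invariance is tested on tie-free data. MDS is Torgerson double-centering
with eigenvector scaling; axis signs are fixed by making each axis's
largest-magnitude coordinate positive; fewer positive eigenvalues than
requested dimensions returns the available ones with a warning.
Over-representation is the hypergeometric upper tail with BH across
pathways (an in-package replacement for external enrichment services).

## Lipid and scalar normalisation

Every lipid species is divided by the sample's summed anchor-class
(default CL) concentration and rescaled by the cohort-mean anchor total to
keep units; anchor totals are exactly equal afterwards and within-sample
ratios are untouched. `content_normalise` returns per-sample ratios only;
aggregation is left to the caller because the ratio of group means is not
the mean of ratios.

## Pipeline

Stages run in fixed order (inputs → MPE → BESt → DE → lipids → structure
→ report); each stage's tables are persisted with sidecar parameter JSON
before the next starts, and a failure raises `StageError` naming the
stage. A single global seed fans out per stage as
SHA-256(`"<seed>:<stage>"`) mod $2^{31}$. The recovery report scores
sensitivity and observed FDP against planted truth, the clustering ARI on
planted features, and the MPE trajectory error; with no planted effects
the truth is flagged degenerate and sensitivity is undefined rather
than zero.

## Problem sizes

Defaults used throughout the tests and the acceptance script: 1500
proteins (600 mitochondrial), 10 participants x 4 timepoints, 300 lipid
species; 10 seeds for bias-removal and recovery summaries, 5 for cluster
recovery, 20 for the marker-stability comparison; 1000 permutations
(exhaustively enumerated where the space is small). These sizes mirror
the reference cohort's scale while keeping a full verification run in the
minutes range on a single CPU.
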