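# Methods

This note records the models, estimators, parameter choices and known
limitations behind `pcovms`.

## Fragment chemistry

All masses are monoisotopic. Residue masses and the proton
(1.00727646677 Da), water (18.01056468 Da) and CO (27.99491462 Da)
constants come from `pyteomics.mass`. Fragment neutral masses follow the
standard low-energy CID series: b = Σ residues (+ retained modification
deltas), y = Σ + water, internal b-type = bare Σ, internal a-type =
internal b − CO; m/z = (M + z·m_H⁺)/z. Coordinates are 1-based inclusive
peptide positions; protein-space labels (K5, K8, K12, K16 for the H4
4–17 peptide at parent offset 4) are display-only. Neutral losses,
immonium ions and isotopologues are deliberately out of scope: the
degeneracy analysis concerns backbone fragments.

Enumeration is exhaustive: b₁..b_{n−1}, y₁..y_{n−1}, internal spans all
(s, e) with 2 ≤ s < e ≤ n−1, each at charges 1..`max_charge`
(default 1). Exact identities used as test invariants: neutral(b_i) +
neutral(y_{n−i}) = peptide mass, and internal(s, e) = b_e − b_{s−1}.

## Digestion and isomer enumeration

Trypsin cleaves C-terminal to K/R except before P; Glu-C cleaves after E
(optionally D). A cleavage-blocking modification (acetyl-K by default,
Δm = +42.010565 Da) suppresses cleavage at modified sites, so candidate
peptides include spans whose internal cut sites are modifiable; a
specific isomer is a consistent digestion product when its unmodified
internal cut sites do not exceed the missed-cleavage allowance. Isomer
sets hold all C(k, m) site combinations in lexicographic order; all
members share the precursor mass exactly.

## Uniqueness (marker) analysis

1D signature: the set of fragment m/z values an isomer can emit
(terminal b/y by default; internal ions by flag). 2D signature: all
unordered pairs of fragments with **disjoint residue spans** — the pairs
one precursor dissociation can co-produce — restricted to
terminal/terminal (b with y) and terminal/internal pair kinds;
internal/internal pairs are excluded. A signal is a marker for an isomer
iff no other isomer of the set produces it within tolerance. Two
tolerance regimes exist on purpose:

* **in-silico degeneracy** is exact, tolerance 1e-6 Da — combinatorial
  isomer degeneracy is a mass-identity, independent of instrument;
* **experimental matching** uses ±0.3 Th (unit-resolution ion trap);
  markers offered to the map matcher are additionally required to be
  unique out to the interrogation reach (matching tolerance + apex
  refinement + integration window), else another isomer's genuine
  correlation within map resolution could masquerade as the marker.

## The microscan generator

Per scan: a global factor g ~ LogNormal(0, σ_TIC) rescales all
precursor rates (the common-mode confound the partial covariance must
remove); each mixture component contributes N ~ Poisson(g·λ) precursor
ions; each precursor picks a fragmentation channel by its branching
ratio or stays undetected; a channel deposits **all** its products into
the scan — this co-deposition is the only source of genuine
fragment–fragment correlation. Products land as Gaussian profiles
(σ = 0.12 Th) on a uniform grid (0.2 Th bins by default), plus additive
detector noise, clipped non-negative. Identical seeds give
byte-identical ensembles.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| total precursors/scan | 100 | ion-count-controlled (AGC-style) trap acquisition |
| microscans | 10⁴ | the acquisition scale the method targets |
| σ_TIC (log-normal) | 0.3 | a strong source/injection fluctuation; synthetic choice |
| channel policy | uniform over all valid pairs | no measured branching ratios exist; documented as synthetic |
| dissociation probability | 0.8 | most precursors fragment at resonance CID |
| peak σ / bin width | 0.12 Th / 0.2 Th | unit-resolution profiles, ~2-bin peaks |
| noise SD | 0.05 counts/bin | small detector floor |

The default channel policy gives every isomer one channel per
complementary-or-shorter b/y pair and one per disjoint
terminal/internal pair, with uniform branching. For the H4 4–17 peptide
this spreads 80 dissociations over 663 channels (~0.03 co-events per
channel per scan) — a deliberately hard, maximally non-committal regime.
Real CID concentrates intensity in a few dominant channels, so real
marker correlations are much stronger than these synthetic ones; passing
the end-to-end tests here is evidence the statistics work at the dilute
extreme, not a calibration of real instrument behaviour. The generator
does not model ion-trap physics (space charge, resonance ejection),
isotope envelopes or chromatography.

## Partial-covariance estimation

The full map is

    pCov(x, y) = Cov(X_x, X_y) − Cov(X_x, T) Cov(T, X_y) / Var(T)

with sample covariances over scans and T the per-scan TIC
(`estimator="tic"`). Because the interrogated channels themselves (and
their co-produced partners) contribute to T, conditioning on the full
TIC partially subtracts genuine correlations; `estimator=
"self_correcting"` conditions on T′ = T − X_x − X_y instead, expanded in
closed form from the same sufficient statistics. On pure common-mode
data both estimators vanish identically (the self-correcting form is
degenerate on the diagonal when one channel is exactly half the TIC; the
diagonal is excluded from all analyses anyway).

**Window volumes and scores.** Peak volumes integrate the map over a
(2w+1)² window (w = 2 for detection, w = 1 for marker interrogation —
a 3×3 window at 0.2 Th bins covers the full 0.12-Th-σ profile). The
jackknife score is V/σ_JK with σ_JK the delete-one-block standard
deviation over 100 contiguous scan blocks, computed from per-block
sufficient statistics (each leave-one-out volume is O(w²)). σ_JK = 0
yields a +inf sentinel with a warning, never a silent division.

For scored volumes the self-correcting form goes further:

* the conditioning variable excludes **both window slices** (tails
  included), so none of the peak's own deposits sit in the regressor;
* the common-mode variance in the correction term is estimated by the
  covariance of two *half-TICs* built from alternating 10-Th m/z chunks
  with 3-bin guard bands. The two halves carry independent shot noise,
  so their covariance is an unbiased estimate of the confound variance —
  an instrumental-variables correction that removes the attenuation a
  noisy TIC proxy leaves behind. Without it, peak volume grows
  super-linearly with precursor rate (residual common-mode ∝ rate²);
  with it, volume vs rate is linear through the origin (R² ≥ 0.999 over
  a 16-fold rate range). When the halves are uncorrelated (no confound)
  the estimator falls back to plain T′ conditioning.

**Known limitation.** With ion counts of ~100 per scan, the Poisson
variance of the TIC is a material fraction of Var(T), and the classical
full-map estimator retains an errors-in-variables residual of roughly
20 % of the plain covariance at fragment-pair coordinates. The 10-fold
off-peak suppression property is therefore measured (and holds, ratio
≈ 0.02) in the confound-dominated regime — dense spectra or strong TIC
fluctuation — which is the regime the correction exists for. Scored
window volumes do not suffer this residual thanks to the split-TIC
correction above.

## Identification and calibration

`identify_isomers` interrogates, for every candidate isomer, its
theoretical unique marker pairs (cleanest first, ranked by an a-priori
contamination proxy: the product of theoretical channel loads at the two
coordinates; 10 markers per isomer by default), snapping each to the
local apex within one bin and jackknife-scoring it.

Because single markers are weak in the dilute uniform-branching world
(SNR ~ 2–5), presence is decided on **combined evidence**: a Stouffer
combination of the isomer's marker scores, standardised against an
empirical null from ~200 decoy coordinates — fragment-m/z pairs that no
candidate isomer can co-produce. Decoy scores depend systematically on
coordinate contamination (busier coordinates are pulled down harder), so
the null is modelled as a linear function of log channel load and each
marker is standardised within its own load stratum. An isomer is called
present when its calibrated combined score exceeds 3 null standard
deviations; the per-marker threshold rule (any marker above a fixed
score) remains available via `match_markers` for strongly correlated
data. The 3σ rule implies a per-isomer false-positive rate of roughly
10⁻³; occasional boundary calls are expected at that rate.

Relative quantification uses the median positive matched-marker volume
per isomer (correlation volume ∝ precursor concentration); the median is
robust against markers whose coordinate aggregates several channels,
which the single-best-volume rule systematically over-weights. On 10⁴
synthetic scans a 70:30 two-isomer mixture is recovered within ~5
percentage points.

## Problem sizes

Tests and the acceptance script run the full chain at the stated
acquisition scale (10⁴ microscans) on m/z windows of 70–750 Th at 0.2 Th
binning (350–3750 channels), which keeps a complete
simulate → map → score → identify cycle at ~10 s and the whole suite
within a few minutes. Uniqueness surveys cap peptides at 10 modifiable
sites by default; wider surveys are a parameter away but grow
combinatorially.
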