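# Methods

This note records the models, conventions and design choices behind
`biooilms`, in the spirit of a statistics package's model documentation.

## Compositions and descriptors

All arithmetic is on **neutral** CHNOS formulas. Negative-ion
electrospray detects deprotonated species, conventionally marked by an
`[H]` suffix on class labels; that suffix is presentation metadata and
never changes an H count. Only C, H, N, O and S are supported — singly
charged monoisotopic species, no isotopologues or adducts.

* **DBE** = c − h/2 + n/2 + 1, returned verbatim even when
  half-integral (odd-electron / odd-nitrogen formulas); erroring here
  would silently bias class tabulations.
* **Van Krevelen point** = (o/c, h/c) as exact ratios; undefined for
  c = 0.
* **Heteroatom class** is the (n, o, s) triple; the coarse groups used
  in distribution tables are Oo, OoSs, NnOo, NnOoSs and HC.
* **Kendrick conversion** uses the exact CH₂ mass 14.0156500641 Da as
  the base (km = mz·14/14.0156500641), so the defect of a CH₂
  homologous series is constant to machine precision; the commonly
  printed factor 14.01565 is this constant rounded and would drift the
  defect by ≈6.4 × 10⁻⁹ per CH₂ unit. The nominal mass is the *nearest*
  integer of the Kendrick mass, keeping defects in (−0.5, 0.5].
* Monoisotopic masses use C = 12 exactly, H = 1.00782503207,
  N = 14.0030740048, O = 15.9949146196, S = 31.97207100 Da.

## Quality filters

Filtering is two-staged in a fixed, order-sensitive sequence: first
assignments with |error| > 0.5 ppm are discarded (absolute value — the
sign encodes calibration direction, the magnitude encodes quality),
then every fine heteroatom class whose summed **relative intensity** is
below 0.15 % of the post-error-filter total is removed as a block.
"Combined relative abundance" is intensity-weighted, the FT-MS
convention, not an assignment-count share. The filter deduplicates any
repeated composition to its most intense occurrence (logged), so
compositions are unique afterwards and the whole operation is
idempotent. The typical assignment window (C 4–500, H 6–200, N 0–4,
O 0–40, S 0–5) is checked as a warning only: published class tables
include abundant sulfur-free classes, so a hard S ≥ 1 floor would be
inconsistent, and real exports occasionally step slightly outside the
advertised window.

## Summaries

Mean element content is the intensity-weighted mean of the element
count, Σ I<sub>i</sub>·count<sub>i</sub> / Σ I<sub>i</sub>, rendered as
a nearest-integer class label ("O14"); an unweighted count-mean is
available as a sensitivity option because the weighting convention in
published mean-oxygen markers is not always stated. M<sub>n</sub> and
M<sub>w</sub> are the intensity-based number- and weight-average m/z;
M<sub>w</sub> ≥ M<sub>n</sub> by Cauchy–Schwarz, with equality iff all
m/z coincide. Printed percentages and ratios use round-half-away-from-
zero at one decimal, matching characterization-table rendering; exact
values are always carried alongside. The derivatized/raw ratio is
computed per class group (a whole-dataset variant is a one-liner on the
totals).

## k-means in van Krevelen space

The feature space is the literal, **unstandardized** (O/C, H/C) plane —
the method interprets Euclidean distance in that plane chemically, and
rescaling would distort it (a z-scaling flag exists, default off).
Points are unweighted; cluster sizes count formulas, so duplicate VK
coordinates from distinct formulas are retained as distinct points.
Nitrogen-containing and non-monoisotopic assignments are excluded
before clustering by default.

The fitter is **Hartigan–Wong**: after a vectorized Lloyd phase
converges, single-point transfers are applied whenever
n₂·d(x, c₂)²/(n₂+1) < n₁·d(x, c₁)²/(n₁−1), best-improvement first
(lowest point index on ties), with incremental centroid updates, until
no improving transfer exists. This fixed point is at least as strong as
Lloyd's — the test suite includes cases where it strictly beats
scikit-learn's Lloyd-based inertia. Singleton clusters are never
emptied by a transfer; empty clusters arising in the Lloyd phase are
re-seeded at the point farthest from its centroid (deterministic under
the seed). Restart initialization draws k distinct points uniformly;
the best of `n_starts` restarts (default 25) by total within-SS wins,
first-found on ties, so fits are bit-reproducible given (point order,
seed, n_starts).

**Model selection** combines two published criteria: the elbow of the
within-SS curve and a between_SS/total_SS ≥ 0.80 threshold. The elbow
is automated as the maximum second difference of the within-SS curve
over the candidate k values (the published procedure reads it
visually; a manual `--k` override exists). The chosen k is the smallest
candidate at or past the elbow whose BSS ratio meets the threshold;
when none does, the elbow k is returned with an explicit warning in the
selection trace. Defaults k ∈ 2..10 and n_starts = 25 are declared
choices — the published workflow states neither. Note the interaction
of the two criteria: for tight, well-separated clusters in 2-D the BSS
ratio saturates early (merging two of five tight clusters still leaves
≥ 86 % between-SS), so the threshold resolves broad, partially
overlapping families — the regime real bio-oil spectra occupy — rather
than idealized point clouds.

## Ward-D2 identity assignment

Centroids and standards are pooled and clustered agglomeratively under
Ward's minimum-variance criterion in its D2 form: the Lance–Williams
recurrence on squared Euclidean dissimilarities,
S(u,w) = ((nᵢ+n_w)S(i,w) + (nⱼ+n_w)S(j,w) − n_w·S(i,j)) / (nᵢ+nⱼ+n_w),
with merge heights √S, so two singletons merge at their Euclidean
distance. Ties take the lowest-index pair. The test suite verifies
exact cophenetic agreement with scipy's independent `ward` linkage.
The headline identity of a centroid is its nearest standard by plain
Euclidean VK distance (quantized at 1e−12 before lexicographic
tie-breaking, ties flagged); the smallest dendrogram clade containing
the centroid and at least one standard is reported as supplementary
context. Newick export places each merge node at half its merge height,
so a height-h pair renders as `(A:h/2,B:h/2);`; labels with reserved
characters are single-quoted.

The fixed-region classifier is an intentionally independent second
path: rectangular VK boxes with explicit per-edge inclusivity. Shipped
regions are "zone 1" (1.5 ≤ H/C ≤ 2, 0 < O/C ≤ 0.3 — half-open at
O/C = 0) and the pyrolytic-lignin box (O/C 0.1–0.67, H/C 0.7–1.5,
closed); others load from a user table.

### The packaged standards table

`data/standards_synthetic.csv` is a **synthetic reconstruction**: the
literature standards list it emulates is not publicly deposited, so the
file collects 25 compounds the bio-oil literature names as constituents
(lignin monomers and phenolics, butanedial, furfural, carbohydrates,
fatty acids, resin acids, terpenoids, sterols) with their true
formulas; humic acid, which has no single molecular formula, carries
representative literature (O/C, H/C) coordinates. On this partial set
the automated elbow + 80 % BSS rule selects **four** clusters (BSS
82.1 %), not the six that a visual elbow reading on the full original
list reports; the discrepancy is documented rather than papered over,
and the corresponding check in the test suite is expected to fail until
a complete standards list is supplied.

## Derivatization matching

DMSO–Ac₂O chemistry is modeled by two formula-resolvable channels:
oxidation (−H₂ per event) and MTM attachment (+C₂H₄S per event).
Ring-MTM and O-MTM attachment are elementally identical and therefore
deliberately unresolved — only the multiplicity m is recorded. For a
product/raw pair the multiplicities are pinned by m = ΔS (with
ΔC = 2m, ΔN = ΔO = 0) and n = (4m − ΔH)/2; defaults bound m ≤ 5 (the
largest attachment count reported in practice) and n ≤ 3 (no published
bound for repeated oxidation of polyols; three events is a generous
polyol allowance). Acetylation (+C₂H₂O) is reported to be a minor
channel and is off by default, available as an option. Matching a
derivatized dataset enumerates, for every product, all raw precursors
compatible with some (m, n) — a dictionary lookup over at most
(max_mtm+1)·(max_ox+1) candidate compositions per product, so matching
is linear in dataset size. Products are reported as matched (all
candidates listed; multiply-explained products flagged), **unreacted**
(the product composition itself occurs in the raw dataset — a
chemically meaningful category, counted as explained), or unexplained.
The whole-dataset matcher is this package's operationalization of
reasoning that is usually applied qualitatively at the
class-distribution level.

The hydration reference line defaults to slope +2 through the origin:
sign conventions for this reference line vary in the literature (±2
for the same line), and only +2 makes "below the line" consistent with
−H₂ oxidation of near-line carbohydrates; the slope is a parameter so
the other convention can be forced. Side-of-line calls
use a 1e−9 tolerance band for "on".

## Synthetic data

`generate_fraction_dataset` draws each assignment from a weighted
archetype: a carbon number uniform in the archetype's range, fuzzed
(O/C, H/C) from per-axis Gaussians, then the nearest integer (h, o) at
that carbon number — so generated VK points carry both Gaussian spread
and integerization noise, as real formula grids do. Compositions are
unique (collisions resample), m/z is the exact neutral monoisotopic
mass restricted to 150–1800 Da, intensities are log-normal (no
published intensity distribution exists; log-normal matches the
heavy-tailed dynamic range of FT-ICR peak lists), and assignment errors
are Gaussian (σ = 0.15 ppm) truncated at ±0.5 ppm, emulating
post-calibration residuals. `simulate_derivatization` draws m from a
user distribution over 0..5 and an oxidation event Bernoulli(p_ox),
redrawing up to 20 times if a product formula collides so the reaction
ledger stays exactly recoverable.

The shipped `demo_ws_profile` places five archetypes at near-equidistant
VK positions (minimum center separation 0.53) with per-axis sd 0.12 —
broad, partially overlapping families rather than point clouds. That
spread is deliberate twice over: it is what real fraction spectra look
like, and it is the regime in which the elbow + BSS selection rule can
resolve all five families (see the k-means section). Archetype centers
are illustrative geometry evoking carbohydrate-, terpenoid-, lignin-,
humin- and sugar-alcohol-like families; they are not measured data.

**What passing synthetic tests do not show:** the generators contain no
noise peaks, isotopic envelopes, resolution limits, intensity
nonlinearity or aging kinetics, so green tests certify the analytics,
not instrument robustness. Problem sizes in the test and acceptance
runs (600–2000 assignments, 250–300 points per planted cluster,
10–100 restarts) are the package's chosen desk-scale defaults; the
statistics involved stabilize well below real spectrum sizes.

## Numerical conventions

* Sum-of-squares bookkeeping asserts total = between + within at 1e−8
  relative on every fit.
* Restart and transfer ties break deterministically (first-found best
  restart; lowest index transfer/pair).
* Nearest-standard distances are quantized at 1e−12 before
  lexicographic tie-breaking.
* CLI float output uses fixed `%.10g` rendering; identical config and
  seed give byte-identical artifacts. Library table round-trips use
  shortest-roundtrip rendering so re-reading restores exact values.
* Degenerate inputs fail loudly and specifically: empty point sets,
  k beyond the distinct-point count, fewer than three candidate k
  values for the elbow, zero total intensity for weighted means,
  zero raw counts for ratios.

## Known limitations

* CHNOS only; no adducts, multiple charging or isotopic fine structure.
* The k-selection rule is the declared automation of a visual
  procedure; on small point sets (such as a standards list) the
  automated elbow can sit below a human reading, as documented above.
* MTM vs. O-MTM attachment sites are formula-degenerate by design.
* The matcher assumes the raw dataset contains every precursor; species
  below the detection threshold in the raw run make true products
  unexplainable.
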