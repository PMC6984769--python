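# Methods

This note documents the models and procedures implemented in `rpiforest`,
the parameters that matter, the numerical conventions, and what the
synthetic benchmark does and does not establish.

## Sequence model and sanitization

Sequences are validated against fixed alphabets: the 20 standard one-letter
amino-acid codes, and {A, C, G, U} for RNA. Input is uppercased; in RNA, T
is mapped to U so DNA-style FASTA files work unchanged. Any remaining
out-of-alphabet character (selenomethionine written as X, ambiguity codes,
modified residues from structure-derived sequences) is **dropped** with a
logged warning; a strict mode errors instead. Dropping joins the neighbors
of the removed character, so k-mer windows are formed on the cleaned
sequence. Dropping was chosen over substitution because the affected runs
are short and substitution would invent k-mers that never occur; the policy
is surfaced in logs so users can audit it.

## Conjoint-triad features

The protein spectrum reduces residues to 7 physicochemical groups, numbered
1..7 in the fixed order {AGV}, {ILFP}, {YMTS}, {HNQW}, {RK}, {DE}, {C}, and
counts every window of three successive residues as its ordered group triad
(g1, g2, g3). Frequencies are counts divided by L − 2, the exact number of
windows, so the 343 entries sum to 1 for L ≥ 3. Triads are stored in
lexicographic order, index 49(g1−1) + 7(g2−1) + (g3−1); the classifier is
order-insensitive, but model persistence requires one canonical layout.

The RNA spectrum counts all 256 4-mers over {A, C, G, U}. Its published
normalization divides by N − 2 although a length-N sequence has N − 3
windows, so the entries sum to (N−3)/(N−2) rather than 1. Both conventions
are implemented: `denominator_mode="paper"` (default, reproduces the method
as published and is used everywhere in this package's own results) and
`denominator_mode="exact"` (divides by N − 3). The difference is a uniform
rescaling of one feature block and is immaterial to a tree ensemble, but
the choice is exposed rather than silently corrected.

AAC (20 amino-acid frequencies, alphabetical) and NC (4 base frequencies,
ACGU order) are plain compositions, counts over sequence length.

## Chaos-game representations

**Protein, 12-gon.** Vertices V_k = (cos((k−1)π/6), sin((k−1)π/6)),
k = 1..12, on the unit circle with V1 = (1, 0); the start point is the
center (0, 0). Reading the sequence left to right, each residue moves the
current point halfway toward the vertex of its class; the trajectory has
exactly L points, all of norm ≤ 1 (midpoint maps toward unit-circle
vertices are contractions of the disc).

Residues are assigned to the 12 vertices by a 12-class partition obtained
by splitting within the 7 conjoint-triad groups: {A}, {G}, {V}, {I,L},
{F,P}, {Y,W}, {M}, {T,S}, {H,N,Q}, {R,K}, {D,E}, {C} → vertices 1..12.
Published 24-segment CGR variants differ in this table and no single
canonical partition exists, so the map is treated as configuration (a JSON
override is accepted everywhere the encoder is exposed); the geometry and
counting are independent of the partition choice, and any fixed bijection
of segment labels yields the same classifier up to a column permutation.

The 24-segment histogram uses 12 angular sectors of 30° crossed with 2
radial bands split at r = 0.5 (configurable): sector = 1 + floor(angle/30°)
with the angle measured counterclockwise from the positive x-axis in
[0°, 360°), band 0 for r < 0.5, and segment = 2(sector−1) + band + 1. This
rule yields 24 congruent-by-rotation cells with a one-line deterministic
assignment. Boundary conventions: r = 0.5 belongs to the outer band; an
angle on a sector edge belongs to the higher sector. Because trajectory
points attracted toward a vertex can lie mathematically *on* a sector edge,
angles within 1e-9 degrees of a 30° multiple are snapped to it before the
floor — otherwise boundary membership would depend on sub-ulp differences
between atan2 implementations.

**RNA, unit square.** Vertices A=(0,0), C=(1,0), G=(1,1), U=(0,1), start
(0.5, 0.5) (the square's center, by the same convention as the polygon).
The 16-cell histogram is the 4×4 grid occupancy — exactly the resolution-2
frequency-CGR — row-major from the (0,0) corner, cells half-open with the
top/right boundary clamped into the last row/column.

Histogram frequencies are D_k = L_k/n with n the sequence length; counts
sum to n and frequencies to 1.

## Feature sets and assembly

Five pair encodings are defined, with widths 24 (AAC+NC), 599 (CTF),
40 (CGR), 639 (CTF+CGR), and 663 (CTF+CGR+AAC+NC). Concatenation order is
canonical: families in the order CTF, CGR, AAC, NC; protein block before
RNA block within each family. Column names are stable
(`p_ctf_000`..`p_ctf_342`, `r_ctf_000`.., `p_cgr_01`.., `r_cgr_01`..,
`p_aac_A`.., `r_nc_A`..) and are embedded in persisted models so that a
matrix encoded under a different feature set is rejected at prediction
time by name, not just by width. No feature scaling is applied: random
forests are invariant to monotone per-feature transforms.

## Classifier and model selection

The classifier is a random forest (scikit-learn's implementation) with
*ntree* mapped to the number of trees and *mtry* to the number of features
sampled at each split. Training requires both classes. The per-pair score
is the forest's averaged tree vote for the interacting class; the decision
threshold is 0.5, with a score of exactly 0.5 called interacting.

Cross-validation uses stratified 10-fold partitions (class-ratio
preserving, fold sizes within one of each other, drawn from a fixed seed);
stratification is used because RPI benchmarks are balanced and it reduces
fold variance. Metrics are computed from the pooled out-of-fold confusion
counts and pooled out-of-fold scores; per-fold reports and their mean are
retained alongside, since pooled and averaged fold metrics differ slightly
and both are of interest.

The grid search evaluates every (ntree, mtry) pair by the same CV and
returns the configuration maximizing pooled accuracy; ties break to the
smaller ntree, then smaller mtry (cheaper and less variance-prone models
preferred at equal accuracy). The search ranges are ntree in [300, 500]
and mtry in [1, n]. A dense mtry grid (one point per dimension) is
supported but costly; the default grid keeps the full range at desk scale
with ntree in {300, 350, 400, 450, 500} and ~8 log-spaced mtry values that
always include round(sqrt(n)), the standard forest default.

## Evaluation metrics

Sens = TP/(TP+FN), Spec = TN/(TN+FP), ACC = (TP+TN)/total, and
MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN)). When any MCC
denominator factor is zero the statistic is undefined; the package returns
0 (an uninformative classifier) with a runtime warning. AUC is the rank
(Mann–Whitney) statistic — the probability that a random positive outscores
a random negative, ties counted half — which coincides with the trapezoidal
ROC area and is well-defined under tied scores. ROC points and AUC are
computed by scikit-learn behind this module's surface and are verified in
the test suite against an independent pair-counting oracle.

## Dataset construction from structures

Chains are extracted from PDB-format files (model 1 only), typed by
residue chemistry: all-amino-acid chains become proteins, all-ribonucleotide
chains RNA; DNA, mixed, or unclassifiable polymers are skipped with a
warning, and waters/ions/ligands are ignored. Where alternate conformations
exist, the highest-occupancy conformer of each atom is kept. All deposited
atoms participate in distances, hydrogens included when present.

A protein-RNA chain pair is interacting when at least one atom pair sits
at a distance **strictly below** 3.4 Å (the criterion names two atoms, one
per molecule, which is read as one atom *pair*); the minimum distance and
the number of sub-cutoff contacts are reported. Closest approaches use a
k-d tree and are tested against exhaustive all-pairs computation.

The length filter removes short chains. The published phrasing
("simultaneously shorter than 25 amino acids and 10 bases") is ambiguous
between dropping pairs where *both* chains are short and requiring *each*
chain to meet its threshold; the default is the stricter per-chain reading
(standard in this literature), and `--filter-mode both-short` implements
the literal one. An optional release-date window filters structures by
user-supplied metadata (structure id → ISO date) before contact analysis;
structures without metadata are excluded when a window is requested. The
builder emits positives only and defines no negative-sampling scheme, and
performs no redundancy reduction by sequence identity.

## Synthetic benchmark

The generator emulates a labeled RPI benchmark in which the interaction is
fully determined by sequence content: a pair is positive iff the protein
contains a fixed 6-residue motif AND the RNA a fixed 6-base motif. Motifs
are implanted at uniformly random positions, overwriting an i.i.d. uniform
background, so composition features carry only weak signal and the ordered
k-mer/CGR encoders must do the work; negatives carry at most one motif and
the missing motif is verified absent by rejection resampling, making the
label rule exact before noise. An optional noise rate flips labels
independently. Defaults — 200 pairs, half positive, protein lengths 50–120,
RNA lengths 40–100, zero noise — give a benchmark of roughly the size of
the smaller published RPI sets at lengths where the 343/256-dimensional
spectra are sparse but informative; all quantities derive deterministically
from one seed and outputs are byte-identical across runs.

What this does and does not show: with zero noise a perfect classifier
exists (the two motif-indicator bits), so pooled AUC > 0.9 demonstrates
that encoders and forest propagate a planted sequence signal end to end,
and the permuted-label control (AUC ≈ 0.5) that the pipeline does not
manufacture signal. Real interaction data differ in essentially every
distributional respect — non-uniform residue composition, homology
structure between pairs, many-to-many pair topology, label noise, and
interaction rules that are structural rather than motif-like — so passing
these checks validates the machinery, not biological performance. Headline
accuracies on the published benchmark datasets require those external
datasets and are out of scope here.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at 120–200
pairs with 300-tree forests, sizes chosen so every stage (including two
full 10-fold CVs) completes in well under a minute while leaving the
learnability and null checks statistically unambiguous. Oracle-equivalence
checks use 100–200 random sequences per encoder. Tolerances: exact
equality for counts and histogram integers; `pytest.approx` double
precision for frequencies; the learnability bound AUC > 0.9 and the null
band [0.4, 0.6] are stochastic checks at fixed seeds. Known limitations:
no probability calibration, no alternative classifiers, no gapped k-mers
or multi-resolution CGR pyramids, and PDB-format (not mmCIF) input for the
dataset builder.
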