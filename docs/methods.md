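# Methods

## Macrocycle definition and ring perception

A macrocycle is any molecule containing at least one ring of 9–30 atoms,
both bounds inclusive, giving 22 representable ring-size values. Ring
sizes are taken from the smallest set of smallest rings (SSSR), the same
perception that underlies SMARTS `r<n>` queries: a fused bicyclic whose
envelope ring exceeds 30 atoms but whose SSSR rings are small is *not* a
macrocycle here, and a compound whose SSSR contains two 9–30 rings counts
as a two-ring macrocycle. The scaffold signature is the sorted,
"+"-joined multiset of macro-ring sizes (`"12+14"`), deliberately coarser
than Murcko or graph-canonical scaffolds: it reproduces ring-size
landscape tallies without committing to a scaffold-isomorphism
definition the data cannot support.

Whether fused macro-rings sharing atoms should count as interconnected
rings is genuinely open; the SSSR convention above is this package's
choice and is applied uniformly, so multi-ring classes {1, 2, 3, 4+} are
well defined.

## Peptide-like classification

An amide qualifies as a *ring* amide when the SMARTS
`[NX3]-@[CX3](=[OX1])-@[#6]` matches (both backbone bonds ring bonds)
**and** the amide N and carbonyl C lie together in at least one ring
inside the 9–30 window. The second condition matters: a bare ring-bond
pattern also counts small lactams (caprolactam's amide sits in a 7-ring)
that are not part of any macrocyclic loop. A macrocycle with ≥ 3 ring
amides is peptide-like — the threshold corresponds to the smallest
cyclic tripeptide, cyclo(Gly)₃, whose 9-membered ring carries exactly
three amides. `count_ring_amides(..., ring_scope="any")` exposes the
unrestricted count for comparison, since published conventions differ.

## Identifiers, descriptors, fingerprints

Deduplication keys on the standard InChIKey; stereochemistry-aware or
tautomer-canonicalized dedup is out of scope. Salts/mixtures are kept as
delivered (desalting is an opt-in pre-processing flag at the ingest
level). Descriptors are SlogP, TPSA, average molecular weight, rotatable
bonds, H-bond donors and acceptors. Donors are counted as donor heavy
atoms — each N or O carrying ≥ 1 H counts once, so water has one donor —
rather than per-hydrogen or per-SMARTS-match conventions; acceptors use
the toolkit default perception. Fingerprints are hashed Morgan/ECFP,
radius 3, 2048 bits.

## Curation cascade

Stages, in the recorded order: macrocycle filter → nanomolar-unit filter
→ interval-relation filter → dedup → (unique-structure count) → one-ring
restriction (on by default, switchable) → activity threshold → pChEMBL.

Numerical and policy choices:

- **No unit conversion.** Only records with `standard_units == "nM"` and
  a present value survive; converting µM/M/µg·mL⁻¹ records would change
  the cascade's meaning. Conversion exists behind an off-by-default flag.
- **"Above 10 µM" is strict.** A value of exactly 10 000 nM is kept
  (pChEMBL 5.0); `threshold_inclusive=False` switches to ≥.
- **Dedup tie-break.** Among records sharing (InChIKey, target, type,
  value) the survivor is the lexicographically smallest
  (document_id, assay_id) — an arbitrary but reproducible rule. Records
  of the same pair with different types (IC50 vs Ki) or values are never
  merged; `mixed_type_duplicates` lists them for manual review, since
  automated merging of heterogeneous endpoints is not defensible.
- **Percentages** are one decimal, round-half-up (`decimal` arithmetic,
  not binary-float rounding), and always recomputable from the stored
  integer counts.
- pChEMBL = 9 − log₁₀(value in nM); the round trip p ↦ value ↦ p is
  exact to 1e−9 over p ∈ [1, 12].

Unparsable SMILES are flagged and excluded with a count in the report,
never silently dropped.

## Parametric t-SNE

The high-dimensional neighbor distribution uses Gaussian kernels on
squared Euclidean distances between fingerprint vectors (Jaccard is
available; its distances are squared as well before kernelization, so
both metrics share the bandwidth-calibration code path). Per-point
bandwidths are found by binary search on the kernel precision until the
conditional distribution's perplexity (2^entropy) matches the target
within 1e−3 (the search iterates to a tighter internal tolerance, at
most 200 steps, and fails loudly naming the point otherwise).
Symmetrization: p_ij = (p_{j|i} + p_{i|j}) / 2n. The low-dimensional
kernel is Student-t with one degree of freedom, fixed, not learned.

The projector is an MLP with layers 2048–500–500–2000–2 (the classic
parametric t-SNE layout; fully configurable), rectifier hidden units, a
linear 2D output, He initialization, and Adam (lr 1e−3). P is computed
per minibatch (batch size min(500, n)) rather than globally, trading a
slightly biased objective for linear scaling; remainder batches too
small to calibrate (≤ perplexity points) are skipped. Early
exaggeration multiplies P by 4 for the first 25 % of epochs to let
clusters separate before fine-tuning. Defaults: perplexity 30 (reduced
to (n−1)/3 by the CLI when data are few), 300 epochs. All randomness
(initialization, batch order) flows from one seed through a single
generator, so training is bit-reproducible on a fixed platform.

Because the network is a pure function of its weights, held-out
compounds are projected by a forward pass (the *parametric* property).
Exact reproduction of any previously published map's coordinates is out
of scope — that would require the original pretrained weights; map
*quality* is asserted instead via trustworthiness (k = 12), silhouette
against planted labels, and intra- vs inter-cluster map distances.
Trustworthiness delegates to scikit-learn's implementation and is
cross-checked in the tests against a brute-force rank-based oracle.

Aggregated activity per map point is the **median pChEMBL** per
(structure, family), a robust choice where the aggregation rule is
otherwise unconstrained.

## Familiarity

Synonym counts per compound proxy recognition; ≥ 5 synonyms (boundary
inclusive, switchable) flags a compound as well-known. Lookup failures
are recorded as *absent*, never coerced to zero, and such records stay
unclassified. The elbow detector (maximum discrete second difference on
the ascending sorted count curve) is advisory only — the classification
threshold stays at five — and a flat curve yields an explicit no-elbow
flag rather than a degenerate suggestion.

## Synthetic fixtures: what they do and do not emulate

The generators plant exact ground truth: single n-rings (size forced),
cyclo(Gly)_k (ring 3k, amides k — both analytically forced, which is why
the glycine homopolymer was chosen), cascade tables whose stage counts
equal a declared plan (each filter gets a dedicated planted group), and
clustered binary fingerprints (uniform random prototypes, mutual Hamming
≈ n_bits/2, members flipped at 2 % per bit — within-cluster distance
≈ 80 bits vs between ≈ 1000 at 2048 bits). Every generator is a pure
function of its arguments including the seed.

They do **not** emulate real bioactivity data: no assay noise or
inter-assay disagreement, no correlated scaffold series, no heavy-tailed
value distributions, no salt forms or stereoisomer duplicates. Passing
tests therefore demonstrate that the machinery is correct on structures
with known answers, not that mining a live database reproduces any
particular published tally; full-database reproduction requires the
corresponding database snapshot and is outside the default suite.

Test and acceptance problem sizes — 60–75 points for embeddings, 50
points for calibration checks, 20-record cascade plans, ring sweeps over
n = 3..40 — are the package's chosen fixture scales: large enough that
every asserted property is non-trivial, small enough to keep the suite
fast and deterministic.

## Known limitations

- SSSR ring perception makes ring-size multisets dependent on the
  toolkit's SSSR tie-breaking for exotic fused systems.
- The nM-only filter discards valid measurements recorded in other
  units; this is a fidelity choice, not a data-quality judgment.
- Minibatch P is not the global t-SNE objective; with batch ≥ n (the
  default at fixture scale) they coincide.
- The familiarity statistic depends on the synonym source's curation
  habits and is not a literature-frequency measure.
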