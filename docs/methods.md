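# Methods

`pepspr` implements a sequence-structure ("structure-property relationship",
SPR) approach to classifying missense variants — in the motivating use case,
amino-acid substitutions (AAS) in a kinase drug target that confer or do not
confer inhibitor resistance. The idea is to treat each substitution not as a
feature vector of physicochemical properties but as a *chemical structure*:
the short mutant peptide around the substituted residue, drawn as a
structural formula and described by substructural atom-centered descriptors.

## From substitution to structure

For a substitution at sequence position *p* and a chosen odd window length
*L*, the training instance is the mutant peptide covering positions
*p − (L−1)/2 … p + (L−1)/2* with the alternate residue applied at the
center. Near a terminus the window is truncated asymmetrically; it is never
padded, because padding would invent atoms and therefore descriptors. The
wild-type window is not used as a paired instance — the class label attaches
to the mutant structure alone.

Peptides are assembled from neutral amino-acid templates (explicit
hydrogens, kekulized rings) by condensation: each peptide bond removes the
carboxyl OH of the N-side residue and one amine H of the C-side residue
(net −H₂O), leaving free NH₂/COOH termini. Protonation is uniformly neutral
— including Asp/Glu/Lys/Arg side chains, with His fixed as the Nε2–H
tautomer and Cys a free thiol — a determinism-over-realism choice: no pKa
model is consulted, so identical sequences always yield identical graphs.
Stereochemistry is not encoded; bond orders are stored for file fidelity
only.

## MNA descriptors

A structure is described by its set of Multilevel Neighborhoods of Atoms
(MNA) descriptors. The level-0 descriptor of an atom is its *mark*: the
element symbol, prefixed "-" when the atom lies on no ring, suffixed
"[±n]" for nonzero formal charge (the charge suffix is this package's
convention; with neutral construction it never fires on standard input).
The level-k descriptor is `mark(D₁D₂…Dd)` where the Dᵢ are the neighbors'
level-(k−1) descriptors concatenated in lexicographic string order. Bond
types are ignored throughout. Two structures are equivalent iff their
descriptor *sets* are equal; multiplicities are kept only for diagnostics.

Descriptor strings grow roughly like (mean degree)^level, which is
intractable to materialize at level 15 on a 31-mer. The implementation
therefore interns descriptors in a shared vocabulary keyed by
(mark, id-sorted children): because the string grammar is uniquely
decodable, structural identity in the vocabulary coincides exactly with
string equality, and integer ids substitute for strings everywhere
downstream. Strings are rendered — with the true lexicographic neighbor
ordering — only for display, dumps and the oracle tests, which compare the
fast path against a direct string-recursion reference at levels 0–6.

## The classifier

For class A (resistant) with prior P(A) = Nk/N and per-descriptor
conditionals P(A|Dᵢ) = Nik/Ni (simple frequency estimates, no smoothing —
arcsin(±1) is finite so degenerate probabilities are admissible):

    S₀ = 2·P(A) − 1
    S  = sin( meanᵢ asin(2·P(A|Dᵢ) − 1) )
    B  = (S − S₀) / (1 − S·S₀)

The mean runs over the m query descriptors known to the training set;
descriptors never seen in training are excluded and reported as the
"new descriptor" count, a coarse applicability-domain measure (a query
whose descriptors are all new gets B = 0 and an out-of-domain flag).
B ∈ [−1, 1]; B = 0 when the query's evidence matches the prior. The
singular point S = S₀ = ±1 is defined as B = 0.

Leave-one-out scores are exact and cheap because the counts are additive:
removing structure s with label y maps N→N−1, Nk→Nk−y and, for s's own
descriptors only, Ni→Ni−1, Nik→Nik−y. The test suite verifies the decrement
path equals naive retraining *exactly*.

**Pa/Pi calibration.** Pa (membership in the resistant class) and Pi
(non-resistant) are computed as mid-rank empirical CDFs of the LOO B-score
distributions of the two training classes:

    Pa(B) = (#{positives with LOO score < B} + ½·ties) / Nk
    Pi(B) = (#{negatives with LOO score > B} + ½·ties) / (N − Nk)

This makes Pa non-decreasing and Pi non-increasing in B, interprets them as
error probabilities of the first/second kind, and makes Pa > Pi a proper
crossing criterion — the default decision rule. The exact calibration used
by the original PASS lineage of software is unpublished; this empirical-CDF
construction is the package's own convention and the main fidelity caveat
when comparing Pa/Pi values (not rankings) against other implementations.

## Evaluation and model selection

ROC AUC is the Mann–Whitney pair statistic with half-weighted ties,
computed on raw B-scores (monotone-equivalent to Pa − Pi under the
calibration above, hence independent of it). Model selection mirrors the
method itself: a grid over window lengths (3–31 odd) × descriptor levels
(1–15), each cell scored by LOO AUC averaged over endpoints, best cell by
maximum average with ties broken toward smaller level, then smaller length.
k-fold CV uses stratified, seeded fold assignment (classes shuffled
separately and dealt round-robin, the second class offset so remainders
spread over folds); k = N reduces exactly to LOO. Threshold scans report
confusion counts and sensitivity/specificity/balanced accuracy at the
Pa > Pi rule and fixed Pa cut-offs 0.3–0.9; a rate whose margin is empty is
reported as NaN rather than an error.

## Synthetic study conditions

The generator emulates a curated resistance training set: one random
protein (default 1000 residues, uniform composition; a natural-frequency
mode exists behind `composition="natural"`), 660 substitution positions
sampled without replacement, positive fraction 84/660 ≈ 12.7%. In `motif`
mode the label depends on sequence context: substitutions with a motif
residue (default tryptophan) within ±2 positions of the site (center
excluded — the mutant window no longer contains the reference residue) are
positive with probability `signal_strength` (default 0.95), others with a
floor probability solved so the expected positive fraction hits the target.
When `signal_strength × hit-rate` already exceeds the target (true at the
defaults: uniform composition gives a hit rate of 1 − (19/20)⁴ ≈ 0.185),
the floor clamps to zero and the hit probability is rescaled downward to
meet the target in expectation. `none` mode draws labels independently of
context for null checks.

What this does and does not show: the planted signal is exactly the kind of
feature an MNA description of a centered window can encode (residue
identity near the center), so recovery (LOO AUC ≈ 0.94–0.96 at window 5)
demonstrates that the pipeline is wired correctly end to end — not that
real resistance data are this learnable. Real training sets carry
positional clustering, composition bias, correlated substitutions and label
noise that the generator deliberately omits. Measured null-label LOO AUC is
unbiased with a single-seed spread of about ±0.05 at n = 660.

## Numerical choices and problem sizes

- Arcsine arguments are exact in [−1, 1] by construction; B is clamped
  against last-bit excursions.
- Descriptor-sort tie-break: byte-wise lexicographic on strings ("-" sorts
  before letters), realized internally by id-sorted canonical multisets.
- Duplicate (position, alt) records are retained with a warning; nonstandard
  residues (U, O, X) are a hard error (no template exists).
- Grid-search cells share one descriptor encoding per window length
  (levels computed incrementally in a single pass).
- The bundled verification runs use the default study conditions (660
  records) for single-cell checks and a reduced 3-length × 3-level grid for
  the selection demonstration; the full 15 × 15 grid is available through
  `pepspr grid` and scales linearly in cells.

## Known limitations

- Pa/Pi values are calibration-convention-dependent (rankings and AUC are
  not).
- Neutral protonation and a fixed His tautomer mean descriptor sets can
  differ from structures prepared under physiological protonation rules;
  `read_sdf` normalizes foreign files only by filling implicit hydrogens.
- Aromatic (type-4) bonds in input SD files must be kekulized; the reader
  rejects them rather than guessing a Kekulé assignment.
- Windows are linear fragments: no disulfides, no cyclic peptides.
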