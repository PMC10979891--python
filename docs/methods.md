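# Methods

## Model

Epitope tag insertion is modeled as a purely positional problem: given a
query protein, every residue position receives a suitability score built
from four per-residue feature tracks, each normalized to [0, 1] so that
higher always means "more tolerant of an inserted peptide".

* **Conservation.** Shannon entropy of the position's MSA column,
  `H_i = -Σ_a p(a) log2 p(a)` in bits, divided by the maximum possible
  entropy over the 20 standard amino acids, `log2(20) ≈ 4.3219` (printed as
  4.32). Gap characters are excluded from the column distribution and the
  probabilities renormalized over the residues present; this keeps the
  normalization constant exactly `log2(20)` (treating the gap as a 21st
  symbol would not). An all-gap column yields a missing value. The query
  itself is counted as a member of its column. Entropy is assigned per
  *query* position through the column map; columns where the query is
  gapped belong to no query position.
* **Secondary structure.** The DSSP code binned as coil `C → 1`, defined
  structure `G/H/I/E → 0` (helices and strands are expected to be fragile
  under insertion), and all remaining codes `→ 0.5`. Only `{C}` and
  `{G,H,I,E}` are explicit in the scheme; the newer polyproline-II code `P`
  and the bridge/turn/bend codes `B/T/S` fall in the 0.5 "otherwise" bin.
  Blank and `-` codes canonicalize to `C`.
* **Solvent accessibility.** `RSA_i = SASA_i / SA_max(residue type)`, using
  the theoretical maximum accessible surface areas of Tien et al. (2013)
  (shipped as `data/max_sasa.tsv`). Empirical SASA can exceed the
  theoretical maximum, so RSA is clamped to 1; the clamp keeps the
  normalized-track contract. Both choices (theoretical maxima; clamping)
  are package decisions and are configurable through the table argument.
* **Disordered binding regions.** The ANCHOR2 probability `BR_i` that the
  residue takes part in a disordered protein-binding interaction, read from
  IUPred2A text output (4-column long dialect or a minimal 2-column
  dialect, auto-detected). The feature is `1 − BR_i`. The predictor is
  consumed as input, never reimplemented.

Per position, the weighted sum `S_i = w1·H_i/4.32 + w2·SS_i + w3·RSA_i +
w4·(1−BR_i)` is reported for inspection (defaults `w = (1.5, 1, 1, 1)`,
emphasizing conservation), and the tagging score `E_i = min(...)` of the
four *unweighted* values drives ranking — the minimum is printed unweighted
and we follow that. A high minimum requires every feature to be favorable
simultaneously.

## Smoothing and site selection

`E_i` is smoothed with a centered moving average, window 7 (odd; one
residue on either side of a typical short tag insertion footprint). At the
sequence edges the window shrinks to the available positions rather than
padding — zero-padding would artificially depress terminal scores. Missing
values are excluded from each local mean; a window of only missing values
stays missing. Smoothing is applied to the minimum track, not to the
features before the minimum (which reproduces a single smooth profile
curve); pre-minimum smoothing is available behind
`build_profile(smooth_features_first=True)`.

Sites are selected greedily from the smoothed track: take the maximum
(ties break toward the more N-terminal position, for determinism), suppress
all positions within `min_separation = 8` residues (about one window) so
the top-k list cannot collapse onto a single peak, repeat. Positions with
any missing feature, and positions whose residue is the unknown letter X
(no SA_max value exists), are excluded from selection. Reported positions
are 1-based; "site at position i" is interpreted as insertion immediately
after residue i — the convention is stated in every report header, since
insertion semantics (before/after/replace) are otherwise ambiguous.

## Inputs and fallbacks

The reference structural input is a DSSP output file (classic fixed-width
format via Biopython's parser, or the mmCIF-DSSP dialect via gemmi), which
supplies both the SS code and the SASA estimate (ACC field). When only a
PDB/mmCIF structure is available the package computes SASA itself with a
deterministic Shrake–Rupley method (fixed Fibonacci point sphere, probe
1.4 Å, 960 points/atom — biotite's implementation) and assigns secondary
structure with the P-SEA geometric approximation (biotite `annotate_sse`,
codes restricted to H/E/C). The fallback is labeled non-reference in the
run manifest: it is a different SASA algorithm and a coarser SS assignment
than DSSP, and rankings can shift accordingly. A supplied DSSP file always
takes precedence.

Structure→sequence mapping matches residues by order after a pairwise
global alignment with an identity check (X matches anything); aligned
non-identical residues are an error naming the first mismatch, and query
positions absent from the structure get missing feature values, never
imputed ones.

Homolog selection takes one best hit per species from standard 12-column
tabular BLAST output: lowest E-value, ties broken by higher bit score and
then lexicographically smallest accession, so the choice is deterministic.
The default panel is seven vertebrates (Bos taurus, Canis lupus, Gallus
gallus, Homo sapiens, Mus musculus, Takifugu rubripes, Xenopus
tropicalis), configurable. All network fetchers (UniProt sequence,
AlphaFold model, IUPred2A track) and external tools (BLAST, aligner, DSSP)
are opt-in and cached to files the offline path consumes; the default mode
is strictly offline and the test suite asserts that the file-based pipeline
makes zero network calls and spawns zero subprocesses.

## Synthetic data

`tagsite.synthetic.make_fixture` writes a complete, internally consistent
input bundle (query FASTA, 8-row aligned FASTA, classic-format DSSP file,
extended-backbone PDB, IUPred2A track) with one planted favorable window of
7 residues: inside it each MSA column cycles through 8 distinct residues
(entropy exactly 3 bits, analytically known because the rotation is fixed,
not sampled), the DSSP file assigns coil with ACC equal to the residue's
SA_max (RSA = 1), and BR = 0.05; outside, columns are perfectly conserved
(entropy 0), structure is helix with ACC = 10, and BR = 0.9. The minimum
feature is therefore ≈ 0.69 inside the window and ≈ 0 outside, and the
smoothed argmax falls on the window center by construction. The seed
controls cosmetic identifiers and the residues *outside* the window — those
carry zero entropy whatever they are, so every analytically known value is
seed-independent while replicate runs still exercise different sequences.

What the fixtures do **not** emulate: realistic protein geometry (the PDB
is an extended backbone; its computed SASA does not match the planted DSSP
ACC values), correlated features, alignment gaps in the query, or noisy
disorder tracks. Passing the planted-peak tests therefore demonstrates the
scoring and selection machinery end-to-end, not predictive performance on
real proteins; the real-protein behavior is exercised by the documented
Smad5 integration example, which needs network access and external tools.

## Numerical choices

* Missing data is NaN everywhere; it propagates through sum and min scores
  and is skipped (not zero-filled) by the smoother and the ranker.
* Entropy uses the convention 0·log2(0) = 0 and is computed from exact
  column frequency tables; agreement with a brute-force implementation is
  asserted to 1e-12.
* Profile serialization prints 17 significant digits, which round-trips
  IEEE doubles bitwise; the human-readable TSV reports 6 decimals.
* Problem sizes in tests and in `scripts/acceptance.py` (60-residue
  queries, 8-row alignments, 20 replicates × 3 peak positions) were chosen
  as the smallest sizes at which every pipeline stage — alignment column
  mapping, fixed-width DSSP parsing, edge-window smoothing, peak
  suppression — is exercised with non-trivial interior and edge behavior.

## Known limitations

* The sum score is computed and reported but does not drive ranking; no
  weight optimization is provided (weights are configuration only).
* The internal SS fallback cannot distinguish 3-10/pi helices, bridges,
  turns or bends; everything non-helix/non-strand maps to coil, which
  biases the fallback toward higher (more permissive) SS scores than DSSP.
* RSA clamping discards information above SA_max; positions with RSA > 1
  are simply "fully exposed".
* Live-database drift can move integration-example results between
  releases of UniProt/AlphaFold/IUPred2A or proteome versions.
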