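# Methods

## The procedure and its assumptions

`crkscan` formalizes the standard genome-wide gene-family survey for DUF26
receptor kinases.  Its input is not raw sequence but *scan evidence*:
tables of domain hits produced by profile-HMM scanners (Pfam-Scan dialect,
InterProScan TSV).  The pipeline therefore assumes that domain detection
itself has been done with curated models, and concentrates on the steps
where published surveys differ and errors creep in — candidate filtering,
overlap cleanup, architecture construction, and classification.

Family membership is defined operationally: at least one DUF26
(`Stress-antifungal`, PF01657) hit passing the filter policy.  When the
scanner reports its curated significance flag (the Pfam gathering
threshold), the flag is authoritative; otherwise an E-value cutoff of
1e−3 applies.  This mirrors scanning "with default parameters": the
gathering threshold is the scanner's own notion of a true hit, and the
E-value fallback is deliberately conservative.  InterPro cross-validation
(IPR002902, IPR038408) defaults to *either* — requiring one accepted
accession — because requiring both would silently drop proteins annotated
under only one of the two equivalent DUF26 entries; the mode is a policy
field (`off` / `either` / `both`).

## Overlap resolution

Scanners emit near-duplicate hits (clan cross-matches, repeated models).
Two hits *compete* when their reciprocal overlap exceeds a configurable
fraction (default 0.3 of **both** intervals, tolerant of boundary jitter
while collapsing true duplicates); within a competing group exactly the
best hit survives, under the total order **bit score → E-value → leftmost
start → lexicographic name**, so output is deterministic.  Architectures
must be strictly disjoint for the domain order to be well defined, so any
residual small overlap (≤ the fraction) between survivors is resolved by
trimming the contested residues from the lower-priority hit; a hit trimmed
to nothing is dropped.  The whole operation is idempotent, which the test
suite checks by property.

Fragment merging repairs the opposite artifact — one domain split into two
adjacent hits.  Consecutive same-label hits separated by ≤ 30 residues
merge, keeping the better bit score and the smaller E-value.  30 residues
is safely below real inter-domain linkers in this family while covering
typical split-hit spacings; `0` disables merging.

## The three classification schemes

1. **Major classes**: the label sequence with *consecutive* runs collapsed,
   joined with "–".  Full deduplication would be wrong: the family contains
   both `DUF26–kinase` and the genuinely distinct alternating
   `DUF26–kinase–DUF26–kinase` and `kinase–DUF26–kinase` architectures,
   which only a run-collapse (not a set-of-domains) representation keeps
   apart.
2. **Subclasses**: the full label sequence joined with "__" — a strict
   refinement of scheme 1 (equal subclass strings imply equal major
   strings; property-tested).
3. **Nomenclature**: `prefix(n_DUF26) + core + suffixes` with
   sd/dd/td/qd for 1–4 repeats, core CRRSP/CRK/CRdK, and decoy suffixes
   D/F/P/S (dS for a doubled sugar transporter).  Repeat counts beyond 4
   produce numeric prefixes (`5d`, …) and flag the assignment rather than
   inventing silent names.  Decoy side (N- or C-terminal of the first
   DUF26) is recorded as metadata but does not enter the name: published
   class tables are not consistent about decoy position, and a
   position-blind name is stable under the boundary jitter the cleanup
   tolerates.  Multiple distinct decoys concatenate suffixes in N→C order
   of first occurrence — a deterministic rule for a case the published
   tables never exercise.  The grammar ships with an exact parser;
   `parse(generate(·))` is identity on every architecture with 1–4
   repeats (property-tested), which guards the alphabet against ambiguity
   (e.g. `CRdK` vs `CRK…` and `dS` vs `D`+`S` are disambiguated by
   longest-token matching).

Signal-peptide and transmembrane labels, if present in the hit table, are
ignored by all three schemes: they encode membrane topology, not domain
architecture, and the nomenclature's CRRSP/CRK split is carried by the
kinase domain alone.

## Physicochemical statistics

- **Molecular weight**: sum of free-amino-acid average masses minus one
  water (18.01528 Da) per peptide bond, reported in kDa.  Average (not
  monoisotopic) masses are the convention for the tens-of-kDa values such
  surveys print.
- **GRAVY**: arithmetic mean of Kyte–Doolittle hydropathy values.
- **Charge**: sum of Henderson–Hasselbalch terms over both termini and the
  D/E/C/Y/H/K/R side chains, at pH 7.0 by default (a parameter — databases
  differ and rarely state their choice).
- **pI**: each Henderson–Hasselbalch term is strictly decreasing in pH, so
  net charge has a unique zero crossing in (0, 14); bisection runs to an
  interval of 1e−6 pH units (well inside the 0.002 target), so the charge
  at the reported pI is numerically zero for any composition.
- The pKa set is EMBOSS-style (N-term 8.6, C-term 3.6, C 8.5, D 3.9,
  E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1).  All constants live in editable
  TSV files under `crkscan/data/`, because published surveys pull these
  numbers from databases that do not disclose their tables; absolute pI
  and charge values are only comparable within one constant set.
- Ambiguity code `X` is tolerated: excluded from mass and GRAVY averages
  (with a warning), no ionizable contribution.  Any other non-standard
  letter is an error naming the position.  Empty sequences are errors.

## Genome distribution

Tandem clusters chain consecutive same-chromosome family members when the
distance between nearest gene boundaries is ≤ 250 kb and (when a full gene
set is available) at most 8 non-family genes start between them; clusters
are the transitive closure and singletons are never reported.  Boundary
(not midpoint) distance is robust to very long genes.  The published
surveys describe clustering only qualitatively; these defaults follow
common gene-family practice and are explicit `ClusterPolicy` fields
precisely because they are conventions, not measurements.  A gene sits on
a terminal arm iff its midpoint lies within 25% of the chromosome length
of either end — one unambiguous point per gene, mirror-symmetric by
construction.  Chromosome labels matching scaffold/contig patterns are
pooled as `unplaced`.

## Summary arithmetic

Class × species matrices are exact multiplicities with deterministic
ordering (descending grand total, ties lexicographic).  Percentages round
half-up to one decimal, matching the reporting style of orthogroup
summaries (e.g. 437 genes with 21 unassigned → 95.2%).  Ties for the
largest class return the lexicographically first label with an explicit
tie flag.

## The synthetic-data generator

Defaults emulate the five-species cotton family landscape: species gene
counts 60/74/65/118/120 (total 437) and class frequencies proportional to
the published major-class totals, 13 chromosomes of 60 Mb per species.
Planted domains use realistic spans (DUF26 90–110 aa, kinases 250–290 aa,
decoys 60–120 aa) separated by 35–80 aa linkers.  The linker floor is
deliberately above the 30-residue fragment-merge gap: otherwise genuine
tandem DUF26 repeats would be indistinguishable *by construction* from
scanner fragmentation, and recovery tests would measure the collision of
two defaults rather than correctness.  Background genes are spaced 1 Mb
apart (far beyond the 250 kb cluster criterion) so only planted clusters
can cluster.

Noise models two scanner artifacts: overlapping near-duplicates of planted
hits with strictly lower bit score (must be removed by overlap
resolution) and sub-threshold DUF26 hits on non-family decoy proteins
(must be rejected by the candidate filter).  Every hit carries an origin
flag in the dataset.

The truth table's expected labels are computed by a separate, simpler rule
implementation inside the generator — not by calling the classifier — so
classifier bugs cannot self-validate.  What passing recovery shows: the
pipeline's cleanup and three schemes are exact on hit tables whose noise
matches these two artifact models.  What it does not show: robustness to
real scanner pathologies outside those models (chimeric hits, wildly
shifted boundaries, missing domains), to genuinely novel domain content,
or to proteome-specific annotation quirks — sequences are random residues
and hit scores are draws, not HMM output.

## Determinism and degenerate inputs

Every ordering in the package is total (explicit tie-breaks everywhere);
fixed seeds give byte-identical generator output; re-running any stage on
unchanged input is byte-identical (manifests record counts, not
timestamps).  Empty inputs return empty results with warnings rather than
errors wherever the operation has a sensible empty answer (empty FASTA,
empty hit table, empty summary input); contract violations (duplicate
FASTA ids, malformed table rows, hits past a declared protein length,
unknown chromosome lengths) are errors naming the offending record or
line.

## Known limitations

- The classifier reports signature strings, not the roman-numeral class
  labels of any particular publication: printed roman numerals are
  edition-specific and at least one published table shows internal
  inconsistencies between its text and row labels.
- Candidate filtering consumes scan tables; proteins missed by the
  upstream scanner are invisible to the pipeline.
- Phylogenetic clade assignment and orthogroup inference are out of scope;
  only the summary arithmetic over such tools' printed totals is
  implemented.
- Physicochemical values depend on the shipped constant tables; comparing
  against numbers from other tools requires matching their constants.
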