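# Methods

## Scope and model

`speclean` cleans *annotated* MS/MS spectral libraries: collections of
fragment spectra whose metadata claims a chemical identity (compound name,
SMILES, InChI, InChIKey) together with the measurement context (precursor
m/z, adduct, ion mode, charge, parent mass). The package treats a spectrum
as an immutable value — a harmonized metadata map plus ascending fragment
m/z and non-negative intensity arrays — and a cleaning pipeline as a
sequence of pure filters, each mapping one spectrum to a new spectrum or to
a removal marker. Fragment m/z values are never modified by any filter;
only intensities (base-peak normalization) and spectrum membership change,
and metadata.

All decisions rest on two pieces of chemistry:

1. **Adduct algebra.** `precursor_mz = (x·M + Δ)/|z|`, where M is the
   neutral monoisotopic ("parent") mass, x the molecule multiplier, z the
   charge, and Δ the summed mass of gained minus lost species with
   electron-mass accounting (proton 1.00727646 Da, electron 0.00054858 Da).
   The electron terms are sub-mDa and cost nothing to keep exact. A
   built-in table covers twelve common adducts ([M+H]+, [M−H]−, [M+Na]+,
   [M+K]+, [M+NH4]+, [M+H−H2O]+, [2M+H]+, [M+2H]2+, [M+Cl]−, [M+FA−H]−,
   [2M−H]−, [M−2H]2−, in repair-priority order); any other grammatical
   adduct is parsed and its Δ computed from its gain/loss formulas, so
   unusual adducts are handled without being "common" candidates for
   repair.
2. **Two mass scales.** Monoisotopic masses (most abundant isotope per
   element) define the parent mass; average masses (standard atomic
   weights) exist solely to *detect* the classic mistake of storing a
   molar mass as the parent mass. The element tables cover the 22 elements
   that occur in small-molecule libraries; both scales are unit-tested
   against independent tabulations. No ordering between the scales is
   assumed (selenium's average mass is below its monoisotopic mass).

Structure identity is 2D: each SMILES/InChI is hashed to an InChIKey
(via RDKit) and compared by the first 14-character block; an explicit
InChIKey field contributes its own first block. Stereochemistry is out of
scope by design — library metadata is rarely reliable at that level.

## Filter contract and global order

A filter is any function `Spectrum -> Spectrum | None`. Filters are
registered under stable ids and automatically arranged into a global
order: key harmonization → value harmonization (ion mode, adduct surface
forms) → derivation (adduct out of the compound-name text before anything
consumes the adduct field; parent mass from precursor + adduct) →
intensity normalization → repairs (name-derivation, salt components,
molar-mass, adduct-from-SMILES, annotation conflicts) → requirements.
Consequences:

- declaring the same filter set in any order yields identical output;
- requirements run only after every repair had its chance, so removals
  mean "unrepairable", not "unrepaired";
- a removal is attributed to the *first* failing requirement, which makes
  the report's removal column sum exactly to the number of removed
  spectra.

Three presets nest: `basic` (harmonization only) ⊂ `default` (adds
derivation, base-peak normalization and a precursor-m/z requirement) ⊂
`library_cleaning` (adds all repairs, then all requirements).

## Repairs and their evidence

A repair is applied only when corroborated by at least two metadata
fields; with a single supporting field the spectrum is left for the
requirement filters. Each repair also exists as a `propose_*` function
returning the change and its evidence without applying it (audit mode),
which is how the strip-and-rederive error-rate audit is implemented.

- **Name derivation**: only fires when both SMILES and InChI are missing;
  the first resolver candidate whose monoisotopic mass matches the stored
  parent mass is adopted (resolvers return canonical-first order, making
  the choice deterministic). Resolver failures log a warning and change
  nothing. Lookups go through a TSV cache that is reloadable across runs.
- **Salt components**: all non-empty proper subsets of the ``.``-separated
  components are scored when the full structure's mass misses the parent
  mass; capped at 8 components (≤ 254 subsets — real salts have few
  components, and the cap bounds the powerset). Best = smallest mass
  error, ties to more heavy atoms, then enumeration order (bitmask order
  over components in original sequence). InChI/InChIKey are rederived
  from the surviving components.
- **Molar-mass parent**: fires only in the signature window — parent mass
  off the monoisotopic mass but on the average mass — and rewrites the
  parent mass to the monoisotopic value.
- **Adduct from SMILES**: candidates are the common-adduct table
  restricted to the spectrum's ion mode (both polarities if unknown);
  best mass agreement wins, ties by table priority ([M+H]+/[M−H]− first).
- **Annotation conflicts**: SMILES and InChI are judged by mass against
  the parent mass; an InChIKey carries no computable mass, so it is
  judged by first-block agreement with a mass-matching field. If the
  mass-matching fields single out one structure, the others are cleared
  *and rederived* from it (so the completeness requirement can pass
  afterwards); zero or ambiguous matches change nothing.

## Tunable parameters

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| `mass_tolerance` | 0.1 | Da | accepts unit-resolution library metadata while rejecting different molecules; configurable per filter |
| `n_min` (high peaks) | 5 | fragments | below this a spectrum carries too little information for matching |
| `intensity_fraction` | 0.02 | of base peak | fragments below 2% are treated as noise for the count |
| precursor m/z window | (0, 5000] | Da | generous physical bound; catches placeholder values like 0 and −1 |
| `allow_default_adduct` | off | — | assuming [M+H]+ is precisely the error class the repairs fix; never assumed silently |
| salt component cap | 8 | components | powerset growth bound |

Known edge: for molecules below roughly 150 Da the molar/monoisotopic gap
is smaller than the 0.1 Da default, so an average-mass parent mass can
pass the parent-mass requirement undetected (and, symmetrically, the
molar-mass repair cannot fire). This is documented, not resolved; a
tighter tolerance resolves it at the cost of rejecting unit-resolution
metadata.

## Determinism and serialization

Pipelines are seed-free and deterministic. Written libraries (MGF, MSP,
JSON) use canonical metadata-key order, fixed 6-decimal rendering for m/z
and mass-like values, UTF-8 and `\n`, so a rerun is byte-identical. The
MGF dialect writes `CHARGE` as `1+`/`2-` and `PEPMASS` as the precursor
m/z alone (intensity tuples are tolerated on read, first element used);
MSP `Comment:` text is preserved verbatim under the `comment` key rather
than parsed into vendor-specific subfields. Workflows serialize to YAML
(one mapping per filter, tool version included); loading re-canonicalizes
filter order, rejects unknown ids, and warns on version mismatch.
Metadata keys are harmonized through a packaged, user-editable two-column
alias table; the shipped list is a best-effort superset, not exhaustive.

## Synthetic libraries and what passing means

The generator draws compounds from a packaged table of 31 curated
structures (123–780 Da) whose SMILES/InChI/InChIKey are mutually
consistent and whose masses are precomputed from the element tables (and
cross-checked against RDKit in tests). Clean spectra are exact by
construction: adduct from the table, precursor from exact algebra, 8–40
fragments with at least six above 2% of the base peak. Each error class
perturbs only the fields its repair targets; each spectrum carries exactly
one class, so the expected fate (kept / repaired / removed) is a function
of the class and the ledger is unambiguous ground truth. Multi-error
spectra exist in reality but would make expected fates non-deterministic,
so they are deliberately excluded. The mixed profile (40% clean, 44%
repairable across five classes, 16% removable across three) is an
arbitrary broad exercise of every code path — the real-world class
frequencies in public libraries are unknown.

What the generator does *not* emulate: real fragmentation (peak positions
are uniform below the precursor — the filters under test only read counts
and relative intensities), chimeric spectra, retention time / collision
energy / instrument metadata, resolver ambiguity (the packaged resolver
returns exactly one correct candidate per name, so the strip-and-rederive
audit's 100%-recovered / 0%-wrong result is the synthetic upper bound, not
a real-world error rate), and multi-error metadata. Passing the ledger
tests therefore demonstrates the pipeline's logic is exact under its own
assumptions, not that a public library would be cleaned error-free.

Test and audit problem sizes — 1000-spectrum mixed libraries for the
fate-agreement and with/without-repairs checks, 50×30 for conservation,
500 clean spectra for the audit — were chosen as the smallest sizes at
which every class appears dozens of times; the whole suite runs in well
under a minute on one core.

## Limitations

- Repairs validate against the *parent mass*; a wrong annotation whose
  mass happens to match goes unnoticed. Fragment-level plausibility
  checks against the structure would be the natural extension.
- 2D-only identity: stereo- and isotopologue distinctions are invisible.
- The common-adduct table is a minimal defensible set; it is
  user-extendable but repairs only ever propose adducts from it.
- Libraries are loaded fully into memory; multi-GB streaming is out of
  scope.
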