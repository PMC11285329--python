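# speclean

Reproducible cleaning of annotated MS/MS spectral libraries.

Public tandem-mass-spectrometry libraries are indispensable for compound
identification and for training machine-learning models, but their metadata is
notoriously inconsistent: precursor m/z hides under a dozen key spellings,
parent masses are computed from molar instead of monoisotopic masses, adducts
are left at an unedited default `[M+H]+`, SMILES keep salt counterions the
instrument never measured, and SMILES/InChI/InChIKey sometimes describe
different compounds. Simply discarding every inconsistent spectrum throws away
a large fraction of a library. `speclean` instead **harmonizes** metadata,
**derives** missing fields from other fields, **repairs** broken annotations —
but only when the correction is corroborated by at least two metadata fields —
and only then **removes** spectra that still fail the quality requirements.
Every run produces a per-filter processing report and a YAML workflow file
that reruns the identical pipeline byte-for-byte.

## The model

A library spectrum is a metadata map plus fragment arrays (m/z ascending,
intensities ≥ 0). All cleaning decisions reduce to adduct mass algebra over
two mass scales. For an adduct with multiplier *x* (copies of the neutral
molecule M), charge *z*, and mass shift Δ (charge-carrier masses including
electrons),

```
precursor m/z = (x·M + Δ) / |z|        M = (precursor m/z · |z| − Δ) / x
```

where M is the **parent mass** — the monoisotopic mass of the neutral
molecule (most-abundant isotopes; `[M+H]+` shifts by the proton mass
1.00727646 Da). The **average (molar) mass**, computed from standard atomic
weights, is what erroneously ends up in parent-mass fields and is how that
error class is detected. Structure fields are compared by the first 14
characters of their InChIKeys (the 2D-skeleton hash block); a "mass matches"
decision uses a configurable tolerance (default 0.1 Da).

The filters run in a fixed global order — harmonization → derivation →
intensity normalization → repairs → requirements — so declaring them in any
order gives identical results. The repair filters are:

| filter | evidence required |
| --- | --- |
| `derive_annotation_from_compound_name` | resolver candidate's monoisotopic mass matches the parent mass |
| `repair_smiles_of_salts` | a subset of the SMILES components sums to the parent mass |
| `repair_parent_mass_is_molar_mass` | parent mass matches the SMILES *average* mass but not its monoisotopic mass |
| `repair_adduct_and_parent_mass_based_on_smiles` | a common adduct links precursor m/z to the SMILES monoisotopic mass |
| `repair_not_matching_annotation` | exactly one structure field's mass matches the parent mass |

Because no public-library download can be part of an offline test cycle, the
package ships a synthetic dirty-library generator: every generated spectrum
carries exactly one known error class and a ledger entry stating its correct
fate (`kept_unchanged`, `repaired_then_kept`, `removed`), giving the pipeline
an exact ground truth to be measured against.

## Worked example

```
$ speclean simulate --n 500 --seed 7 --output dirty.mgf --ledger truth.tsv
wrote 500 spectra to dirty.mgf

$ speclean clean --input dirty.mgf --output cleaned.mgf \
    --report report.tsv --workflow workflow.yaml --name-resolver stub
spectra_in=500 spectra_out=422 removed=78 repaired=241
```

The processing report (`report.tsv`) attributes every change to its filter:

```
filter                                         removed  metadata_changed  peaks_changed
harmonize_ionmode                              0        380               0
normalize_intensities                          0        0                 500
derive_annotation_from_compound_name           0        58                0
repair_smiles_of_salts                         0        38                0
repair_parent_mass_is_molar_mass               0        47                0
repair_adduct_and_parent_mass_based_on_smiles  0        55                0
repair_not_matching_annotation                 0        43                0
require_parent_mass_match_smiles               22       0                 0
require_matching_adduct_and_ionmode            21       0                 0
require_minimum_number_of_high_peaks           35       0                 0
```

Reading: 380 spectra had ion-mode spellings normalized and all 500 had
intensities rescaled to the base peak (routine harmonization); 241 spectra
had their *annotation* repaired — e.g. 38 salts lost a counterion and 55
spectra traded an unedited default `[M+H]+` for the adduct that actually
explains their precursor m/z — and would otherwise have been discarded; the
78 spectra no evidence could rescue (wrong parent mass, ion-mode/adduct
contradiction, too few usable fragments) were removed, each counted once at
the first requirement it failed. `workflow.yaml` records the full pipeline;
`speclean clean --input dirty.mgf --workflow workflow.yaml --output rerun.mgf`
reproduces `cleaned.mgf` byte-for-byte.

The same functionality is available as a library:

```python
from speclean import build_preset, run_pipeline, read_library
from speclean.synthetic import table_resolver

spectra = read_library("dirty.mgf")
cleaned, report = run_pipeline(
    spectra, build_preset("library_cleaning"), resolver=table_resolver()
)
```

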