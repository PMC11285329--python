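# Metadata key harmonization table: raw key (after lowercasing and
# punctuation-to-underscore normalization) -> harmonized key.
# Keys not listed here are kept verbatim (lowercased). Edit freely.
pepmass	precursor_mz
precursormz	precursor_mz
precursor_m_z	precursor_mz
precursor_mass	precursor_mz
prec_mz	precursor_mz
ms1_precursor_mz	precursor_mz
exact_mass	parent_mass
exactmass	parent_mass
parentmass	parent_mass
parent_mass	parent_mass
neutral_mass	parent_mass
name	compound_name
compoundname	compound_name
compound	compound_name
common_name	compound_name
molecule_name	compound_name
ion_mode	ionmode
ionmode	ionmode
ionisation_mode	ionmode
ionization_mode	ionmode
polarity	ionmode
precursor_type	adduct
precursortype	adduct
adduct_ion	adduct
ion_type	adduct
inchi_key	inchikey
inchikey_	inchikey
inchiaux	inchi_aux
canonical_smiles	smiles
isomeric_smiles	smiles
molecular_formula	formula
chemical_formula	formula
sum_formula	formula
charge_state	charge
spectrumid	spectrum_id
spectrum_id	spectrum_id
scan_number	scans
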