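"""Optional thin adapter for pulling corpus tables from ChEMBL.

Requires ``chembl-webresource-client`` (not a package dependency) and a
network connection; everything else in the package works from files or
synthetic corpora, and nothing in the tested path imports this module.
The adapter maps ChEMBL molecule records onto :class:`DrugRecord` and
IC50 activities onto :class:`TargetActivity`; protein structural profiles
have no ChEMBL source and must still be supplied as a file.
"""

from __future__ import annotations

from typing import Iterable

from .types import DrugRecord, Label, TargetActivity

_CHEM_FIELDS = (
    "alogp", "cx_logp", "cx_logd", "cx_most_apka", "cx_most_bpka",
    "aromatic_rings", "full_mwt", "mw_freebase", "mw_monoisotopic",
    "hba", "hbd", "hba_lipinski", "hbd_lipinski", "heavy_atoms",
    "num_lipinski_ro5_violations", "num_ro5_violations", "qed_weighted",
    "psa", "rtb",
)


def _client():
    try:
        from chembl_webresource_client.new_client import new_client
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the ChEMBL adapter needs the 'chembl-webresource-client' "
            "package; install it separately or load corpora from files"
        ) from exc
    return new_client


def fetch_drugs(chembl_ids: Iterable[str]) -> list[DrugRecord]:  # pragma: no cover
    """Fetch molecule records and map them onto DrugRecords.

    Withdrawal status comes from the molecule's ``withdrawn_flag``; drugs
    in clinical phases 1-3 without approval map to investigational.
    """
    client = _client()
    records = []
    for mol in client.molecule.filter(molecule_chembl_id__in=list(chembl_ids)):
        props = mol.get("molecule_properties") or {}
        chem = {k: props.get(k) for k in _CHEM_FIELDS if props.get(k) is not None}
        for flag in ("oral", "parenteral", "topical", "prodrug"):
            if mol.get(flag) is not None:
                chem[flag] = bool(mol[flag])
        if props.get("molecular_species"):
            species = str(props["molecular_species"]).lower()
            for cat in ("acid", "base", "neutral", "zwitterion"):
                chem[cat] = species == cat
        if mol.get("withdrawn_flag"):
            label = Label.WITHDRAWN
        elif mol.get("max_phase") and float(mol["max_phase"]) < 4:
            label = Label.INVESTIGATIONAL
        else:
            label = Label.NOT_WITHDRAWN
        structures = mol.get("molecule_structures") or {}
        records.append(
            DrugRecord(
                drug_id=mol["molecule_chembl_id"],
                label=label,
                atc_codes=list(mol.get("atc_classifications") or []),
                smiles=structures.get("canonical_smiles"),
                chem_features=chem,
            )
        )
    return records


def fetch_ic50_activities(chembl_ids: Iterable[str]) -> list[TargetActivity]:  # pragma: no cover
    """Fetch IC50 standard values (nM) against single human protein targets."""
    client = _client()
    out = []
    rows = client.activity.filter(
        molecule_chembl_id__in=list(chembl_ids),
        standard_type="IC50",
        standard_units="nM",
        target_organism="Homo sapiens",
    )
    for row in rows:
        value = row.get("standard_value")
        accession = row.get("target_chembl_id")
        if value is None or accession is None:
            continue
        value = float(value)
        if value <= 0:
            continue
        out.append(TargetActivity(row["molecule_chembl_id"], accession, value))
    return out
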