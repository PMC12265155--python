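"""Synthetic drug corpora with a plantable withdrawal signal.

Emulates the four corpus tables (drugs with descriptors and fingerprints,
drug-protein IC50 records, protein structural profiles, ATC codes) with a
withdrawal signal planted in exactly four controllable ways:

* additive shifts of chosen chemical descriptors in withdrawn drugs,
* elevated probability of activity against designated "toxic" proteins,
* fingerprint bits biased toward the withdrawn class,
* class-dependent ATC level-1 letter frequencies.

Toxic proteins additionally share an elevated helix fraction and contact
count so that structural-feature selection has a recoverable signal.
Investigational (clinical-trial) drugs are drawn from a stated mixture of
the two class distributions; the source class of each is recorded on the
bundle so screening behaviour can be checked against ground truth.

Generation is a pure function of the config (including its seed): one
root seed, split deterministically into independent per-view streams, so
adding drugs to one view never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .fingerprints import fingerprint_bit_names
from .types import DrugRecord, Label, ProteinStructureProfile, TargetActivity

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "PlantedTruth",
    "generate",
    "planted_truth",
    "strong_signal_config",
    "null_config",
]

#: Per-feature (mean, sd) or (low, high) background distributions at
#: plausible small-molecule scales; keeps min-max normalization
#: nondegenerate without any class signal.
_CHEM_BACKGROUND: dict[str, tuple[str, float, float]] = {
    "alogp": ("normal", 2.5, 1.5),
    "cx_logp": ("normal", 2.5, 1.8),
    "cx_logd": ("normal", 1.5, 1.8),
    "cx_most_apka": ("normal", 8.0, 3.0),
    "cx_most_bpka": ("normal", 7.0, 3.0),
    "aromatic_rings": ("poisson", 2.0, 0.0),
    "full_mwt": ("normal", 380.0, 110.0),
    "mw_freebase": ("normal", 350.0, 100.0),
    "mw_monoisotopic": ("normal", 350.0, 100.0),
    "hba": ("poisson", 5.0, 0.0),
    "hbd": ("poisson", 2.0, 0.0),
    "hba_lipinski": ("poisson", 6.0, 0.0),
    "hbd_lipinski": ("poisson", 2.5, 0.0),
    "heavy_atoms": ("normal", 26.0, 8.0),
    "num_lipinski_ro5_violations": ("poisson", 0.4, 0.0),
    "num_ro5_violations": ("poisson", 0.4, 0.0),
    "qed_weighted": ("uniform", 0.1, 0.95),
    "psa": ("normal", 80.0, 30.0),
    "rtb": ("poisson", 5.0, 0.0),
}

_CHEM_FLAG_PROBS: dict[str, float] = {
    "acid": 0.15, "base": 0.35, "neutral": 0.45, "zwitterion": 0.05,
    "prodrug": 0.08, "oral": 0.7, "parenteral": 0.25, "topical": 0.1,
    "ro3_pass": 0.2,
}

_STRUCT_FEATURES = (
    "helix_residues",
    "sheet_residues",
    "turn_residues",
    "disordered_residues",
    "contacts",
    "transmembrane_segments",
    "aggregation_prone_residues",
)

#: Uniform class-agnostic ATC level-1 letter weights (the 14 WHO groups).
_ATC_LETTERS = tuple("ABCDGHJLMNPRSV")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-signal corpus generator."""

    seed: int = 0
    n_drugs: int = 400
    withdrawn_fraction: float = 0.5
    n_proteins: int = 30
    n_toxic_proteins: int = 4
    #: P(activity against a toxic protein) for (withdrawn, not withdrawn).
    toxic_hit_prob: tuple[float, float] = (0.8, 0.1)
    #: P(activity against a non-toxic protein), class-independent.
    background_hit_prob: float = 0.15
    #: Additive shift applied to withdrawn drugs' chem descriptors.
    chem_effect_sizes: Mapping[str, float] = field(default_factory=dict)
    #: (mu, sigma) of ln IC50 in nM.
    ic50_lognormal: tuple[float, float] = (4.0, 1.5)
    n_fingerprint_bits: int = 512
    #: Number of fingerprint bits correlated with the label ...
    fingerprint_signal_bits: int = 0
    #: ... each set with P(1 - flip) in withdrawn, P(flip) in not withdrawn.
    fingerprint_flip_prob: float = 0.15
    #: Background density of non-signal bits.
    fingerprint_background_prob: float = 0.1
    #: Level-1 letter -> (withdrawn prob, not withdrawn prob); letters not
    #: listed share the remaining mass uniformly.
    atc_enrichment: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    n_investigational: int = 0
    #: Mixture weight: P(an investigational drug is drawn from the
    #: withdrawn-class distribution).
    investigational_withdrawn_weight: float = 0.5

    def validate(self) -> None:
        if self.n_toxic_proteins > self.n_proteins:
            raise ValueError("n_toxic_proteins exceeds n_proteins")
        if not 0 < self.withdrawn_fraction < 1:
            raise ValueError("withdrawn_fraction must be in (0,1)")
        probs = [*self.toxic_hit_prob, self.background_hit_prob,
                 self.fingerprint_flip_prob, self.fingerprint_background_prob,
                 self.investigational_withdrawn_weight]
        for letter, (pw, pn) in self.atc_enrichment.items():
            probs += [pw, pn]
            if letter.upper() not in _ATC_LETTERS:
                raise ValueError(f"unknown ATC level-1 letter {letter!r}")
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0,1]")
        if round(self.n_drugs * self.withdrawn_fraction) < 1:
            raise ValueError("config yields no withdrawn drugs")
        if self.fingerprint_signal_bits > self.n_fingerprint_bits:
            raise ValueError("more signal bits than fingerprint bits")


@dataclass
class PlantedTruth:
    """Ground-truth identifiers of the planted signal."""

    signal_chem_features: list[str]
    signal_fingerprint_bits: list[str]
    toxic_proteins: list[str]
    enriched_atc_letters: list[str]
    has_signal: bool
    bayes_rule: str


@dataclass
class SyntheticBundle:
    """One generated corpus: the three record tables plus provenance."""

    drugs: list[DrugRecord]
    activities: list[TargetActivity]
    profiles: list[ProteinStructureProfile]
    truth: PlantedTruth
    #: drug_id -> source class distribution for investigational drugs.
    investigational_sources: dict[str, Label]


def planted_truth(config: SyntheticConfig) -> PlantedTruth:
    """The signal identifiers downstream stages are expected to recover."""
    config.validate()
    chem = sorted(k for k, v in config.chem_effect_sizes.items() if v != 0)
    bit_names = fingerprint_bit_names(config.n_fingerprint_bits)
    bits = bit_names[: config.fingerprint_signal_bits]
    toxic = [_protein_name(i) for i in range(config.n_toxic_proteins)]
    atc = sorted(
        letter.upper()
        for letter, (pw, pn) in config.atc_enrichment.items()
        if pw != pn
    )
    differs_by_hits = config.toxic_hit_prob[0] != config.toxic_hit_prob[1]
    has_signal = bool(chem or bits or atc or (toxic and differs_by_hits))
    if not has_signal:
        rule = "no signal: classes are exchangeable; optimal accuracy 0.5"
    else:
        rule = (
            "classify withdrawn when the evidence favours it: shifted chem "
            f"features {chem}, activity against toxic proteins {toxic} "
            f"(hit probs {config.toxic_hit_prob}), biased fingerprint bits "
            f"{bits}, and enriched ATC letters {atc}"
        )
    return PlantedTruth(
        signal_chem_features=chem,
        signal_fingerprint_bits=bits,
        toxic_proteins=[] if not differs_by_hits else toxic,
        enriched_atc_letters=atc,
        has_signal=has_signal,
        bayes_rule=rule,
    )


def _protein_name(i: int) -> str:
    return f"SYN{i:05d}"


def _stream(config: SyntheticConfig, view: int) -> np.random.Generator:
    # Independent deterministic sub-stream per view.
    return np.random.default_rng([config.seed, view])


def _draw_chem(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for name, (kind, a, b) in _CHEM_BACKGROUND.items():
        if kind == "normal":
            cols[name] = rng.normal(a, b, n)
        elif kind == "poisson":
            cols[name] = rng.poisson(a, n).astype(float)
        else:
            cols[name] = rng.uniform(a, b, n)
    for name, p in _CHEM_FLAG_PROBS.items():
        cols[name] = (rng.random(n) < p).astype(float)
    return cols


def _atc_probs(config: SyntheticConfig, withdrawn: bool) -> np.ndarray:
    explicit = {k.upper(): v for k, v in config.atc_enrichment.items()}
    probs = np.empty(len(_ATC_LETTERS))
    free = [i for i, L in enumerate(_ATC_LETTERS) if L not in explicit]
    mass = 0.0
    for i, L in enumerate(_ATC_LETTERS):
        if L in explicit:
            probs[i] = explicit[L][0 if withdrawn else 1]
            mass += probs[i]
    rest = max(0.0, 1.0 - mass)
    for i in free:
        probs[i] = rest / len(free) if free else 0.0
    return probs / probs.sum()


_REASON_POOL = (
    "Hepatic toxicity", "Cardiotoxicity", "QT prolongation",
    "Nephrotoxicity", "Neurotoxicity", "Abuse",
)


def _make_drugs(
    config: SyntheticConfig,
    rng_chem: np.random.Generator,
    rng_fp: np.random.Generator,
    rng_atc: np.random.Generator,
    ids: list[str],
    withdrawn_mask: np.ndarray,
    labels: list[Label],
) -> list[DrugRecord]:
    n = len(ids)
    chem = _draw_chem(rng_chem, n)
    for name, shift in config.chem_effect_sizes.items():
        if name not in chem:
            raise ValueError(f"unknown chem feature {name!r} in chem_effect_sizes")
        chem[name] = chem[name] + shift * withdrawn_mask

    chirality = rng_chem.choice(
        ["achiral", "racemic", "single_stereoisomer"], size=n, p=[0.5, 0.2, 0.3]
    )

    fp = (rng_fp.random((n, config.n_fingerprint_bits))
          < config.fingerprint_background_prob).astype(np.uint8)
    k = config.fingerprint_signal_bits
    if k:
        p_on = np.where(withdrawn_mask[:, None] == 1,
                        1.0 - config.fingerprint_flip_prob,
                        config.fingerprint_flip_prob)
        fp[:, :k] = (rng_fp.random((n, k)) < p_on).astype(np.uint8)

    pw = _atc_probs(config, withdrawn=True)
    pn = _atc_probs(config, withdrawn=False)
    records = []
    for i, drug_id in enumerate(ids):
        n_codes = 1 + int(rng_atc.random() < 0.3)
        probs = pw if withdrawn_mask[i] else pn
        letters = rng_atc.choice(list(_ATC_LETTERS), size=n_codes, p=probs)
        codes = [f"{L}{rng_atc.integers(1, 17):02d}{'ABCD'[rng_atc.integers(4)]}{rng_atc.integers(1, 100):02d}"
                 for L in letters]
        reasons = []
        if labels[i] is Label.WITHDRAWN:
            n_reasons = 1 + int(rng_atc.random() < 0.3)
            reasons = list(rng_atc.choice(_REASON_POOL, size=n_reasons, replace=False))
        features: dict[str, object] = {name: float(col[i]) for name, col in chem.items()}
        features["chirality"] = str(chirality[i])
        records.append(
            DrugRecord(
                drug_id=drug_id,
                label=labels[i],
                withdrawal_reasons=reasons,
                atc_codes=codes,
                chem_features=features,
                fingerprint=fp[i],
            )
        )
    return records


def _make_activities(
    config: SyntheticConfig,
    rng: np.random.Generator,
    ids: list[str],
    withdrawn_mask: np.ndarray,
) -> list[TargetActivity]:
    mu, sigma = config.ic50_lognormal
    toxic = set(range(config.n_toxic_proteins))
    out = []
    for i, drug_id in enumerate(ids):
        for j in range(config.n_proteins):
            if j in toxic:
                p = config.toxic_hit_prob[0 if withdrawn_mask[i] else 1]
            else:
                p = config.background_hit_prob
            if rng.random() < p:
                ic50 = float(np.exp(rng.normal(mu, sigma)))
                out.append(TargetActivity(drug_id, _protein_name(j), ic50))
    return out


def _make_profiles(config: SyntheticConfig, rng: np.random.Generator) -> list[ProteinStructureProfile]:
    profiles = []
    for j in range(config.n_proteins):
        length = int(rng.integers(200, 1200))
        toxic = j < config.n_toxic_proteins
        helix_frac = rng.uniform(0.45, 0.65) if toxic else rng.uniform(0.15, 0.35)
        contact_rate = rng.uniform(3.5, 4.5) if toxic else rng.uniform(1.5, 2.5)
        sheet_frac = rng.uniform(0.05, 0.25)
        turn_frac = rng.uniform(0.05, 0.15)
        disorder_frac = rng.uniform(0.05, 0.3)
        features = {
            "helix_residues": round(helix_frac * length),
            "sheet_residues": round(sheet_frac * length),
            "turn_residues": round(turn_frac * length),
            "disordered_residues": round(disorder_frac * length),
            "contacts": round(contact_rate * length),
            "transmembrane_segments": float(rng.integers(0, 8 if toxic else 4)),
            "aggregation_prone_residues": round(rng.uniform(0.02, 0.1) * length),
        }
        profiles.append(ProteinStructureProfile(_protein_name(j), length, features))
    return profiles


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Sample one corpus; fully reproducible from ``config`` alone."""
    config.validate()
    truth = planted_truth(config)

    n_withdrawn = int(round(config.n_drugs * config.withdrawn_fraction))
    labels = [Label.WITHDRAWN] * n_withdrawn
    labels += [Label.NOT_WITHDRAWN] * (config.n_drugs - n_withdrawn)
    ids = [f"DRUG{i:05d}" for i in range(config.n_drugs)]

    # Investigational drugs: mixture of the two class distributions.
    rng_mix = _stream(config, 4)
    sources: dict[str, Label] = {}
    inv_ids = [f"TRIAL{i:05d}" for i in range(config.n_investigational)]
    for drug_id in inv_ids:
        src = (Label.WITHDRAWN
               if rng_mix.random() < config.investigational_withdrawn_weight
               else Label.NOT_WITHDRAWN)
        sources[drug_id] = src

    all_ids = ids + inv_ids
    all_labels = labels + [Label.INVESTIGATIONAL] * len(inv_ids)
    withdrawn_mask = np.array(
        [1 if lab is Label.WITHDRAWN else 0 for lab in labels]
        + [1 if sources[d] is Label.WITHDRAWN else 0 for d in inv_ids]
    )

    drugs = _make_drugs(
        config, _stream(config, 0), _stream(config, 1), _stream(config, 2),
        all_ids, withdrawn_mask, all_labels,
    )
    activities = _make_activities(config, _stream(config, 3), all_ids, withdrawn_mask)
    profiles = _make_profiles(config, _stream(config, 5))
    return SyntheticBundle(drugs, activities, profiles, truth, sources)


def strong_signal_config(seed: int = 0, n_investigational: int = 60) -> SyntheticConfig:
    """The shipped strong-signal study condition: 600 drugs, 40 proteins of
    which 6 toxic with hit probabilities (0.8, 0.1), +1.5 alogp shift in
    withdrawn drugs, 8 biased fingerprint bits, and a nervous-system ATC
    enrichment."""
    return SyntheticConfig(
        seed=seed,
        n_drugs=600,
        withdrawn_fraction=0.5,
        n_proteins=40,
        n_toxic_proteins=6,
        toxic_hit_prob=(0.8, 0.1),
        chem_effect_sizes={"alogp": 1.5},
        fingerprint_signal_bits=8,
        fingerprint_flip_prob=0.15,
        atc_enrichment={"N": (0.45, 0.18)},
        n_investigational=n_investigational,
    )


def null_config(seed: int = 0) -> SyntheticConfig:
    """Zero-signal condition: classes exchangeable by construction."""
    return SyntheticConfig(
        seed=seed,
        n_drugs=400,
        withdrawn_fraction=0.5,
        n_proteins=30,
        n_toxic_proteins=4,
        toxic_hit_prob=(0.15, 0.15),
        chem_effect_sizes={},
        fingerprint_signal_bits=0,
        n_investigational=0,
    )
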