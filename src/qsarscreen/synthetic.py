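"""Synthetic structure–activity data with known ground truth.

The generator fabricates desk-scale datasets with the statistical structure a
ligand-based screening pipeline assumes: two structurally distinct scaffold
families (an "active" family sharing closely related cores, emulating a
congeneric inhibitor series, and a heterogeneous low-activity family), an
additive substituent model on the pChEMBL scale

    pChEMBL = base(scaffold) + sum(substituent effects) + N(0, noise_sd)

clipped to the observed activity range, and a target active fraction at the
pChEMBL >= 7 rule.  Defaults mirror a curated inhibitor dataset: activities
spanning 2.72-9.00 with ~57% actives.

Molecules are built by string templating on valence-checked cores: every core
carries `{R1}`/`{R2}` attachment slots filled from a substituent library, and
every assembled SMILES is re-parsed and canonicalised before emission, so all
generated structures are guaranteed parseable without a generative chemistry
model.

`generate_raw_records` runs the activity model backwards through the curation
contract (value = 10^-pChEMBL, random concentration units, log-scale jitter,
optional alternate SMILES encodings), producing raw assay tables that
exercise parsing, unit handling and deduplication end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .curation import BioactivityRecord, canonical_key

# Active family: two closely related fused-bicyclic aminoquinazoline-like
# cores (a congeneric series sharing a core); inactive family: two unrelated
# small aromatic cores. {R1}/{R2} are substitution slots.
ACTIVE_CORES = [
    "c1cc2ncnc(N{R1})c2cc1{R2}",        # 4-aminoquinazoline
    "c1cc2ncnc(N{R1})c2c(C)c1{R2}",     # 5-methyl analogue, same core
]
INACTIVE_CORES = [
    "O=C(N{R1})c1ccc({R2})cc1",          # benzamide
    "O=S(=O)(N{R1})c1cccc({R2})c1",      # benzenesulfonamide
]

#: substituent fragment SMILES -> additive pChEMBL effect.  Effects span
#: roughly +/-0.8 pChEMBL units, a realistic SAR spread for analogue series.
DEFAULT_SUBSTITUENTS: dict[str, float] = {
    "": 0.0,            # H
    "C": 0.1,           # methyl
    "CC": 0.15,         # ethyl
    "C(C)C": 0.05,      # isopropyl
    "OC": 0.3,          # methoxy
    "O": -0.2,          # hydroxyl
    "F": 0.2,           # fluoro
    "Cl": 0.25,         # chloro
    "C(F)(F)F": -0.15,  # trifluoromethyl
    "N": -0.3,          # amino
    "N(C)C": 0.4,       # dimethylamino
    # substituent rings use index 9 so they never collide with the open ring
    # numbers of a core template
    "c9ccccc9": 0.6,    # phenyl
    "Cc9ccccc9": 0.45,  # benzyl
    "C#N": -0.5,        # nitrile
    "[N+](=O)[O-]": -0.8,  # nitro
}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_compounds: int = 400
    active_cores: list[str] = field(default_factory=lambda: list(ACTIVE_CORES))
    inactive_cores: list[str] = field(default_factory=lambda: list(INACTIVE_CORES))
    active_fraction: float = 0.57
    base_pchembl_active: float = 7.6
    base_pchembl_inactive: float = 5.0
    substituents: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUENTS)
    )
    noise_sd: float = 0.4
    clip_range: tuple[float, float] = (2.72, 9.00)
    activity_threshold: float = 7.0

    def __post_init__(self) -> None:
        if self.clip_range[0] >= self.clip_range[1]:
            raise ValueError("clip_range low must be < high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.active_cores) + len(self.inactive_cores) < 2:
            raise ValueError("need at least two scaffold cores")
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must be in (0, 1)")
        # the active family must be able to clear the threshold and the
        # inactive family to stay below it, else the target fraction is
        # structurally unsatisfiable
        max_eff = 2 * max(self.substituents.values())
        min_eff = 2 * min(self.substituents.values())
        if self.base_pchembl_active + max_eff < self.activity_threshold:
            raise ValueError(
                "unsatisfiable active_fraction: active-family ceiling "
                f"{self.base_pchembl_active + max_eff:.2f} is below the "
                f"threshold {self.activity_threshold}"
            )
        if self.base_pchembl_inactive + min_eff >= self.activity_threshold:
            raise ValueError(
                "unsatisfiable active_fraction: inactive-family floor is "
                "at or above the threshold"
            )


@dataclass
class SyntheticCompound:
    """One generated molecule with its ground truth."""

    structure_key: str
    pchembl: float
    scaffold_family: str  # "active" | "inactive"
    core: str
    substituents: tuple[str, str]
    deterministic_pchembl: float  # base + effects, before noise/clip


def _clear_probability(base: float, effects: list[float], threshold: float, noise_sd: float) -> float:
    """P(activity >= threshold) for one family, averaged over substituent pairs."""
    from scipy.stats import norm

    dets = np.array([base + e1 + e2 for e1 in effects for e2 in effects])
    if noise_sd == 0.0:
        return float(np.mean(dets >= threshold))
    return float(np.mean(norm.sf((threshold - dets) / noise_sd)))


def _active_family_size(spec: SyntheticSpec) -> int:
    """Family allocation whose expected active fraction equals the target.

    Solves target = f * p_active_family + (1 - f) * p_inactive_family for the
    active-family share f, using the exact probability that one compound of
    each family clears the threshold (enumerated substituent effects + normal
    noise; the upper clip cannot move a compound across the threshold).
    """
    effects = list(spec.substituents.values())
    p_act = _clear_probability(
        spec.base_pchembl_active, effects, spec.activity_threshold, spec.noise_sd
    )
    p_inact = _clear_probability(
        spec.base_pchembl_inactive, effects, spec.activity_threshold, spec.noise_sd
    )
    if p_act <= p_inact or not p_inact <= spec.active_fraction <= p_act:
        raise ValueError(
            "unsatisfiable active_fraction "
            f"{spec.active_fraction}: family clear-probabilities are "
            f"active={p_act:.3f}, inactive={p_inact:.3f}; adjust bases, "
            "substituent effects or noise_sd"
        )
    share = (spec.active_fraction - p_inact) / (p_act - p_inact)
    return round(share * spec.n_compounds)


def _assemble(core: str, r1: str, r2: str) -> str | None:
    smi = core.replace("{R1}", f"({r1})" if r1 else "").replace(
        "{R2}", r2 if r2 else ""
    )
    # empty R2 slot can leave a dangling position; strip "()" artifacts
    smi = smi.replace("()", "")
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def generate_dataset(
    spec: SyntheticSpec | None = None, seed: int = 0
) -> list[SyntheticCompound]:
    """Generate n unique compounds with known activities.

    Compound counts per family follow the target active fraction; activities
    are base + additive substituent effects + Gaussian noise, clipped to the
    spec range.  Reproducible under seed; the returned metadata (family,
    core, substituents, noise-free activity) supports parameter-recovery
    tests.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    subs = list(spec.substituents)

    n_active = _active_family_size(spec)
    plan = [("active", n_active), ("inactive", spec.n_compounds - n_active)]
    compounds: list[SyntheticCompound] = []
    seen: set[str] = set()
    for family, n_family in plan:
        cores = spec.active_cores if family == "active" else spec.inactive_cores
        base = (
            spec.base_pchembl_active
            if family == "active"
            else spec.base_pchembl_inactive
        )
        made = 0
        attempts = 0
        while made < n_family:
            attempts += 1
            if attempts > 200 * n_family:
                raise RuntimeError(
                    f"cannot assemble {n_family} unique {family} compounds; "
                    "enlarge the substituent library or core list"
                )
            core = cores[int(rng.integers(len(cores)))]
            r1, r2 = (subs[int(rng.integers(len(subs)))] for _ in range(2))
            key = _assemble(core, r1, r2)
            if key is None or key in seen:
                continue
            seen.add(key)
            det = base + spec.substituents[r1] + spec.substituents[r2]
            noisy = det + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0)
            compounds.append(
                SyntheticCompound(
                    structure_key=key,
                    pchembl=float(np.clip(noisy, *spec.clip_range)),
                    scaffold_family=family,
                    core=core,
                    substituents=(r1, r2),
                    deterministic_pchembl=det,
                )
            )
            made += 1
    # interleave families deterministically so file order carries no label
    order = rng.permutation(len(compounds))
    return [compounds[i] for i in order]


def generate_raw_records(
    dataset: list[SyntheticCompound],
    replicate_lambda: float = 0.0,
    unit_mix: tuple[str, ...] = ("nM", "uM"),
    jitter_sd: float = 0.0,
    alternate_smiles: bool = False,
    seed: int = 0,
) -> list[BioactivityRecord]:
    """Emit a raw assay table consistent with a dataset's ground truth.

    Each compound yields 1 + Poisson(replicate_lambda) records whose values
    are 10^-pChEMBL mol/L re-expressed in a randomly chosen unit, optionally
    jittered on the log scale and re-encoded as non-canonical SMILES.
    """
    unit_scale = {"nM": 1e9, "uM": 1e6, "mM": 1e3, "M": 1.0}
    for u in unit_mix:
        if u not in unit_scale:
            raise ValueError(f"invalid unit in unit_mix: {u!r}")
    rng = np.random.default_rng(seed)
    records: list[BioactivityRecord] = []
    for idx, comp in enumerate(dataset):
        n_rep = 1 + int(rng.poisson(replicate_lambda))
        for rep in range(n_rep):
            p = comp.pchembl + (rng.normal(0.0, jitter_sd) if jitter_sd else 0.0)
            unit = unit_mix[int(rng.integers(len(unit_mix)))]
            value = 10.0 ** (-p) * unit_scale[unit]
            smiles = comp.structure_key
            if alternate_smiles:
                mol = Chem.MolFromSmiles(smiles)
                smiles = Chem.MolToSmiles(
                    mol, canonical=False, doRandom=True
                )
            records.append(
                BioactivityRecord(
                    compound_id=f"SYN{idx:05d}",
                    smiles=smiles,
                    endpoint_type="IC50",
                    qualifier="=",
                    value=value,
                    unit=unit,
                )
            )
    return records


def generate_library(
    spec: SyntheticSpec | None = None,
    n: int = 200,
    overlap_fraction_with_actives: float = 0.5,
    seed: int = 0,
) -> tuple[list[str], dict[str, str]]:
    """Generate a screening library with ground-truth family tags.

    A stated fraction of molecules is built from the active scaffold family
    (what a good model should retrieve); the rest are decoys from the
    inactive family.  Returns (SMILES list, key -> family map).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= overlap_fraction_with_actives <= 1.0:
        raise ValueError("overlap fraction must be in [0, 1]")
    spec = spec or SyntheticSpec()
    lib_spec = SyntheticSpec(
        n_compounds=n,
        active_cores=spec.active_cores,
        inactive_cores=spec.inactive_cores,
        active_fraction=min(max(overlap_fraction_with_actives, 0.01), 0.99),
        base_pchembl_active=spec.base_pchembl_active,
        base_pchembl_inactive=spec.base_pchembl_inactive,
        substituents=spec.substituents,
        noise_sd=spec.noise_sd,
        clip_range=spec.clip_range,
    )
    compounds = generate_dataset(lib_spec, seed=seed)
    truth = {c.structure_key: c.scaffold_family for c in compounds}
    return [c.structure_key for c in compounds], truth


def within_between_tanimoto(
    dataset: list[SyntheticCompound], config=None
) -> tuple[float, float]:
    """Mean within-family vs between-family Tanimoto (structure check)."""
    from .fingerprints import FingerprintConfig, fingerprint_matrix

    config = config or FingerprintConfig()
    keys = [c.structure_key for c in dataset]
    fams = np.array([c.scaffold_family == "active" for c in dataset])
    matrix, _ = fingerprint_matrix(keys, config)
    M = matrix.matrix.astype(np.int32)
    inter = M @ M.T
    pop = M.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    sims = inter / np.maximum(union, 1)
    same = fams[:, None] == fams[None, :]
    off_diag = ~np.eye(len(keys), dtype=bool)
    within = float(sims[same & off_diag].mean())
    between = float(sims[~same].mean())
    return within, between
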