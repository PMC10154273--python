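"""Synthetic twin/family data with known variance fractions.

Emulates the structure of a large developmental cohort with an embedded
twin sub-sample: families of MZ twins, DZ twins, full-sibling pairs and
singletons, one or two annual-visit timepoints two years apart, fixed
effects of age, sex and a practice (repeat-assessment) dummy, and
optionally SNP-like measurement noise around the pedigree kinship values.
Every draw is reproducible from the config seed, and the truth manifest
records the generative fractions alongside realized twin correlations so
recovery tests have an explicit target.

The phenotype is generated from the same covariance model the engine
fits: per family, A is drawn jointly from the kinship block, C is shared
by the family, T by the pregnancy, S by the subject across visits, and E
is independent per observation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .relatedness import (
    RelatednessMatrix,
    SubjectRecord,
    build_kinship_grm,
    derive_pregnancy_id,
)

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "simulate_dataset",
    "perturb_grm",
]

_EFFECTS = ("A", "C", "T", "S", "E")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for one synthetic dataset.

    fractions: true variance shares over {A, C, T, S, E}; omitted effects
    are 0 and the set must sum to 1. Ages are in months (baseline uniform
    on [107, 132], visit 2 shifted by +24); fixed-effect sizes are in
    phenotype units (per month for age_slope). grm_noise_sd perturbs
    within-family kinship values to mimic a SNP-derived matrix.
    """

    n_mz: int = 0
    n_dz: int = 0
    n_sib: int = 0
    n_singleton: int = 0
    n_visits: int = 1
    fractions: dict[str, float] = field(
        default_factory=lambda: {"A": 0.6, "C": 0.2, "E": 0.2}
    )
    total_variance: float = 1.0
    mu: float = 0.0
    age_slope: float = 0.0
    sex_effect: float = 0.0
    practice_effect: float = 0.0
    grm_noise_sd: float = 0.0
    seed: int = 0

    def full_fractions(self) -> dict[str, float]:
        f = {e: float(self.fractions.get(e, 0.0)) for e in _EFFECTS}
        return f

    def validate(self) -> None:
        f = self.full_fractions()
        unknown = set(self.fractions) - set(_EFFECTS)
        if unknown:
            raise ValueError(f"unknown effect(s) in fractions: {sorted(unknown)}")
        if any(v < 0 for v in f.values()):
            raise ValueError(f"fractions must be nonnegative: {f}")
        if abs(sum(f.values()) - 1.0) > 1e-8:
            raise ValueError(f"fractions must sum to 1, got {sum(f.values())}")
        if min(self.n_mz, self.n_dz, self.n_sib, self.n_singleton) < 0:
            raise ValueError("family counts must be nonnegative")
        if self.n_visits not in (1, 2):
            raise ValueError(f"n_visits must be 1 or 2, got {self.n_visits}")
        if f["T"] > 0 and self.n_mz + self.n_dz == 0:
            raise ValueError("T fraction > 0 requires MZ or DZ twin pairs")
        if f["S"] > 0 and self.n_visits != 2:
            raise ValueError("S fraction > 0 requires n_visits = 2")
        if self.total_variance <= 0:
            raise ValueError("total_variance must be positive")
        if self.grm_noise_sd < 0:
            raise ValueError("grm_noise_sd must be nonnegative")
        n_fam = self.n_mz + self.n_dz + self.n_sib + self.n_singleton
        if n_fam == 0:
            raise ValueError("at least one family required")


@dataclass
class TruthManifest:
    """Config echo plus realized quantities a recovery test checks."""

    config: SimulationConfig
    n_obs: int
    n_subjects: int
    n_families: int
    r_mz: float | None
    r_dz: float | None
    r_sib: float | None
    subject_effects: pd.DataFrame | None = None

    def to_json(self) -> str:
        d = {
            "config": asdict(self.config),
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "n_families": self.n_families,
            "realized_twin_correlations": {
                "r_mz": self.r_mz, "r_dz": self.r_dz, "r_sib": self.r_sib,
            },
        }
        return json.dumps(d, indent=2)


def _pair_correlation(values: dict[str, float], pairs: list[tuple[str, str]]):
    if len(pairs) < 3:
        return None
    x = np.array([values[a] for a, b in pairs])
    y = np.array([values[b] for a, b in pairs])
    # double-entered: each pair contributes both orderings (standard for
    # twin correlations, symmetric in pair member order)
    x2 = np.concatenate([x, y])
    y2 = np.concatenate([y, x])
    return float(np.corrcoef(x2, y2)[0, 1])


def simulate_dataset(
    config: SimulationConfig, *, keep_effects: bool = False
) -> tuple[pd.DataFrame, RelatednessMatrix, TruthManifest]:
    """Generate (phenotype table, relatedness matrix, truth manifest).

    The table is long format, one row per (subject, visit), with columns
    subject_id, family_id, visit, birth_date, zygosity, age, sex, pheno.
    The relatedness matrix is kinship-derived unless grm_noise_sd > 0, in
    which case it is a SNP-like perturbation of the kinship values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    f = config.full_fractions()
    sig = config.total_variance

    subjects: list[SubjectRecord] = []
    pair_class: list[tuple[str, str, str]] = []  # (class, id_a, id_b)
    fam_counter = 0

    def _dates(rng, n_distinct):
        year = 2008 + int(rng.integers(0, 3))
        months = rng.choice(12, size=n_distinct, replace=False) + 1
        days = rng.integers(1, 28, size=n_distinct) + 0
        return [f"{year:04d}-{m:02d}-{d:02d}" for m, d in zip(months, days)]

    for kind, count in (("MZ", config.n_mz), ("DZ", config.n_dz),
                        ("SIB", config.n_sib), ("SGL", config.n_singleton)):
        for _ in range(count):
            fam_counter += 1
            fid = f"F{fam_counter:05d}"
            if kind in ("MZ", "DZ"):
                (date,) = _dates(rng, 1)
                a, b = f"{fid}_1", f"{fid}_2"
                subjects += [
                    SubjectRecord(a, fid, date, kind),
                    SubjectRecord(b, fid, date, kind),
                ]
                pair_class.append((kind, a, b))
            elif kind == "SIB":
                d1, d2 = _dates(rng, 2)
                a, b = f"{fid}_1", f"{fid}_2"
                subjects += [
                    SubjectRecord(a, fid, d1, None),
                    SubjectRecord(b, fid, d2, None),
                ]
                pair_class.append(("SIB", a, b))
            else:
                (date,) = _dates(rng, 1)
                subjects.append(SubjectRecord(f"{fid}_1", fid, date, None))

    grm = build_kinship_grm(subjects)
    preg = derive_pregnancy_id(subjects)

    sid = [s.subject_id for s in subjects]
    n_sub = len(sid)
    pos = {s: k for k, s in enumerate(sid)}

    # subject-level latent draws
    a_eff = np.zeros(n_sub)
    c_eff = np.zeros(n_sub)
    t_eff = np.zeros(n_sub)
    s_eff = rng.standard_normal(n_sub) * np.sqrt(sig * f["S"])

    fams: dict[str, list[int]] = {}
    for s in subjects:
        fams.setdefault(s.family_id, []).append(pos[s.subject_id])
    for members in fams.values():
        K = grm.values[np.ix_(members, members)]
        L = np.linalg.cholesky(K + 1e-10 * np.eye(len(members)))
        a_eff[members] = np.sqrt(sig * f["A"]) * (L @ rng.standard_normal(len(members)))
        c_eff[members] = np.sqrt(sig * f["C"]) * rng.standard_normal()
    preg_draw: dict[str, float] = {}
    for s in subjects:
        p = preg[s.subject_id]
        if p not in preg_draw:
            preg_draw[p] = rng.standard_normal() * np.sqrt(sig * f["T"])
        t_eff[pos[s.subject_id]] = preg_draw[p]

    base_age = rng.uniform(107.0, 132.0, size=n_sub)
    # twins share a birth date hence an age at visit
    for members in fams.values():
        by_date: dict[str, list[int]] = {}
        for i in members:
            by_date.setdefault(subjects[i].birth_date, []).append(i)
        for same in by_date.values():
            base_age[same] = base_age[same[0]]
    sex = np.where(rng.random(n_sub) < 0.5, "F", "M")
    # twin pairs are sex-concordant (MZ necessarily; DZ mirrors the
    # same-sex recruitment of registry twin samples)
    for s in subjects:
        if s.zygosity is not None:
            members = fams[s.family_id]
            sex[members] = sex[members[0]]

    rows = []
    rand_part = []
    for visit_idx in range(config.n_visits):
        e_eff = rng.standard_normal(n_sub) * np.sqrt(sig * f["E"])
        for k, s in enumerate(subjects):
            age = base_age[k] + 24.0 * visit_idx
            practice = float(visit_idx > 0)
            g = a_eff[k] + c_eff[k] + t_eff[k] + s_eff[k] + e_eff[k]
            y = (
                config.mu
                + config.age_slope * age
                + config.sex_effect * (sex[k] == "M")
                + config.practice_effect * practice
                + g
            )
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "family_id": s.family_id,
                    "visit": "baseline" if visit_idx == 0 else "year2",
                    "birth_date": s.birth_date,
                    "zygosity": s.zygosity if s.zygosity else "",
                    "age": age,
                    "sex": sex[k],
                    "pheno": y,
                }
            )
            rand_part.append(g)
    table = pd.DataFrame(rows)

    # realized twin correlations on the baseline random part
    base_vals = {s.subject_id: rand_part[k] for k, s in enumerate(subjects)}
    r = {
        kind: _pair_correlation(
            base_vals, [(a, b) for kk, a, b in pair_class if kk == kind]
        )
        for kind in ("MZ", "DZ", "SIB")
    }

    out_grm = grm
    if config.grm_noise_sd > 0:
        out_grm = perturb_grm(
            grm, config.grm_noise_sd, seed=int(rng.integers(0, 2**31 - 1))
        )

    eff_frame = None
    if keep_effects:
        eff_frame = pd.DataFrame(
            {"subject_id": sid, "A": a_eff, "C": c_eff, "T": t_eff, "S": s_eff}
        )
    manifest = TruthManifest(
        config=config,
        n_obs=len(table),
        n_subjects=n_sub,
        n_families=fam_counter,
        r_mz=r["MZ"],
        r_dz=r["DZ"],
        r_sib=r["SIB"],
        subject_effects=eff_frame,
    )
    return table, out_grm, manifest


def perturb_grm(
    grm: RelatednessMatrix, noise_sd: float, seed: int = 0
) -> RelatednessMatrix:
    """Jitter a kinship matrix into a SNP-like one.

    Within-family off-diagonal entries get zero-mean Gaussian noise of sd
    ``noise_sd``; MZ entries (kinship 1) are resampled until they stay
    above the 0.9 MZ-detection threshold; the diagonal is jittered with
    sd/2 around 1. Between-family zeros stay exactly zero (genotype noise
    across families is irrelevant once the matrix is family-sparsified).
    """
    if grm.source != "kinship":
        raise ValueError("perturb_grm expects a kinship-derived matrix")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    V = grm.values.copy()
    if noise_sd == 0:
        return RelatednessMatrix(ids=list(grm.ids), values=V, source="snp")
    rng = np.random.default_rng(seed)
    n = V.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    related = V[iu, ju] > 0
    for i, j in zip(iu[related], ju[related]):
        base = V[i, j]
        val = base + rng.normal(0.0, noise_sd)
        if base == 1.0:  # MZ pair: keep above the 0.9 detection threshold
            while not (0.9 < val <= 1.5):
                val = base + rng.normal(0.0, noise_sd)
        val = float(np.clip(val, -0.5, 1.5))
        V[i, j] = V[j, i] = val
    d = 1.0 + rng.normal(0.0, noise_sd / 2.0, size=n)
    np.fill_diagonal(V, np.clip(d, 0.8, 1.2))
    return RelatednessMatrix(ids=list(grm.ids), values=V, source="snp")
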