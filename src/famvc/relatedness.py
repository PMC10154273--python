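"""Genetic relatedness for family-clustered samples.

Builds kinship-derived relatedness matrices from pedigree/zygosity labels
(MZ twins = 1, DZ twins and full siblings = 0.5, unrelated = 0), ingests
SNP-derived matrices as supplied, derives pregnancy IDs (shared family ID
and birth date) for twin-status random effects, sparsifies any relatedness
matrix into family blocks, and expands per-family blocks to the
observation level for longitudinal designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "RelatednessMatrix",
    "SparseClusteredGRM",
    "derive_pregnancy_id",
    "build_kinship_grm",
    "sparsify_by_family",
    "expand_to_observations",
]


@dataclass(frozen=True)
class SubjectRecord:
    """One sampled individual.

    Parameters
    ----------
    subject_id : str
        Unique identifier within a table of subjects.
    family_id : str
        Family cluster label; relatedness between members of different
        families is treated as zero.
    birth_date : str or None
        Calendar date (ISO-8601) or opaque label; same family + same
        birth date defines a shared pregnancy.
    zygosity : {"MZ", "DZ", None}
        Twin zygosity where known (twin sub-sample members), else None.
    """

    subject_id: str
    family_id: str
    birth_date: str | None = None
    zygosity: str | None = None

    def __post_init__(self):
        if self.zygosity not in (None, "MZ", "DZ"):
            raise ValueError(
                f"zygosity must be 'MZ', 'DZ' or None, got {self.zygosity!r} "
                f"for subject {self.subject_id!r}"
            )


def subjects_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    """Build SubjectRecords from a table with subject_id/family_id columns.

    Optional columns: birth_date, zygosity (missing/NA -> None). Duplicate
    subject_id rows are collapsed to their first occurrence.
    """
    sub = df.drop_duplicates(subset="subject_id")
    recs = []
    for row in sub.itertuples(index=False):
        bd = getattr(row, "birth_date", None)
        zg = getattr(row, "zygosity", None)
        recs.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                family_id=str(row.family_id),
                birth_date=None if pd.isna(bd) else str(bd),
                zygosity=None if (zg is None or pd.isna(zg) or zg == "") else str(zg),
            )
        )
    return recs


def _check_unique_ids(subjects: list[SubjectRecord]) -> None:
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject_id values: {dupes}")


def derive_pregnancy_id(
    subjects: list[SubjectRecord], *, on_missing_birth_date: str = "error"
) -> dict[str, str]:
    """Assign a pregnancy ID to every subject.

    Two subjects share a pregnancy ID iff they have the same family ID and
    the same birth date; everyone else (including singletons) gets a unique
    one.

    Parameters
    ----------
    subjects : list of SubjectRecord
    on_missing_birth_date : {"error", "own"}
        With "error" (default) a missing birth date is rejected naming the
        subject; with "own" the subject becomes its own pregnancy (a
        warning is emitted) so the twin-status effect stays well defined.

    Returns
    -------
    dict mapping subject_id -> pregnancy_id
    """
    _check_unique_ids(subjects)
    out: dict[str, str] = {}
    missing = [s.subject_id for s in subjects if s.birth_date is None]
    if missing:
        if on_missing_birth_date == "error":
            raise ValueError(
                f"missing birth_date for subject(s): {missing}; "
                "cannot derive pregnancy IDs"
            )
        if on_missing_birth_date != "own":
            raise ValueError(
                f"on_missing_birth_date must be 'error' or 'own', "
                f"got {on_missing_birth_date!r}"
            )
        warnings.warn(
            f"{len(missing)} subject(s) without birth_date assigned "
            "singleton pregnancy IDs",
            stacklevel=2,
        )
    for s in subjects:
        if s.birth_date is None:
            out[s.subject_id] = f"preg::own::{s.subject_id}"
        else:
            out[s.subject_id] = f"preg::{s.family_id}::{s.birth_date}"
    return out


@dataclass
class RelatednessMatrix:
    """Symmetric subject-by-subject genetic relatedness.

    Kinship scale: MZ twins 1, full-sibling expectation 0.5. ``source``
    records whether entries come from pedigree expectations ("kinship") or
    from genotypes ("snp"); SNP-derived entries may be slightly negative or
    overshoot 1 and the diagonal may deviate from 1.
    """

    ids: list[str]
    values: np.ndarray
    source: str = "kinship"

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in relatedness matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("relatedness matrix not symmetric (tol 1e-12)")
        if self.source == "kinship":
            ok = np.isin(self.values, (0.0, 0.5, 1.0))
            if not ok.all():
                bad = np.argwhere(~ok)[0]
                raise ValueError(
                    "kinship-derived entries must be 0, 0.5 or 1; found "
                    f"{self.values[tuple(bad)]} at {tuple(bad)}"
                )
            if not (np.diag(self.values) == 1.0).all():
                raise ValueError("kinship-derived diagonal must be 1")
        elif self.source == "snp":
            if self.values.min() < -0.5 or self.values.max() > 1.5:
                raise ValueError(
                    "snp-derived entries must lie in [-0.5, 1.5]; found "
                    f"range [{self.values.min():.3f}, {self.values.max():.3f}]"
                )
            d = np.diag(self.values)
            if d.min() < 0.8 or d.max() > 1.2:
                raise ValueError(
                    "snp-derived diagonal must lie in [0.8, 1.2]; found "
                    f"range [{d.min():.3f}, {d.max():.3f}]"
                )
        else:
            raise ValueError(f"source must be 'kinship' or 'snp', got {self.source!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, subject_id: str) -> int:
        try:
            return self.ids.index(subject_id)
        except ValueError:
            raise KeyError(f"subject {subject_id!r} not in relatedness matrix")

    def subset(self, keep_ids: list[str]) -> "RelatednessMatrix":
        idx = [self.index_of(i) for i in keep_ids]
        return RelatednessMatrix(
            ids=list(keep_ids),
            values=self.values[np.ix_(idx, idx)],
            source=self.source,
        )


def build_kinship_grm(
    subjects: list[SubjectRecord],
    *,
    pair_overrides: dict[tuple[str, str], float] | None = None,
) -> RelatednessMatrix:
    """Pedigree-expectation relatedness: 1 for MZ pairs, 0.5 otherwise
    within family, 0 between families.

    Follows the all-full-siblings assumption: every non-MZ within-family
    pair gets 0.5. ``pair_overrides`` maps unordered subject-id pairs to a
    coefficient for half/adopted siblings etc.; overridden values must
    still be on the kinship grid {0, 0.5, 1}.
    """
    _check_unique_ids(subjects)
    ids = [s.subject_id for s in subjects]
    by_id = {s.subject_id: s for s in subjects}
    n = len(ids)
    V = np.zeros((n, n))
    np.fill_diagonal(V, 1.0)

    fams: dict[str, list[int]] = {}
    for k, s in enumerate(subjects):
        fams.setdefault(s.family_id, []).append(k)

    for members in fams.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                si, sj = subjects[i], subjects[j]
                mz = (
                    si.zygosity == "MZ"
                    and sj.zygosity == "MZ"
                    and si.birth_date == sj.birth_date
                )
                if si.zygosity == "MZ" and sj.zygosity == "MZ" and not mz:
                    raise ValueError(
                        f"inconsistent zygosity: subjects {si.subject_id!r} and "
                        f"{sj.subject_id!r} both labeled MZ in family "
                        f"{si.family_id!r} but have different birth dates"
                    )
                V[i, j] = V[j, i] = 1.0 if mz else 0.5

    if pair_overrides:
        for (a, b), val in pair_overrides.items():
            if val not in (0.0, 0.5, 1.0):
                raise ValueError(
                    f"override for pair ({a!r}, {b!r}) must be 0, 0.5 or 1, got {val}"
                )
            if a not in by_id or b not in by_id:
                missing = a if a not in by_id else b
                raise KeyError(f"override references unknown subject {missing!r}")
            if by_id[a].family_id != by_id[b].family_id:
                raise ValueError(
                    f"override pair ({a!r}, {b!r}) spans two families"
                )
            i, j = ids.index(a), ids.index(b)
            V[i, j] = V[j, i] = val

    return RelatednessMatrix(ids=ids, values=V, source="kinship")


@dataclass
class SparseClusteredGRM:
    """Family-sparsified relatedness: per-family blocks, implied zero
    between families (the sparse-clustering trick that makes the phenotypic
    covariance block-diagonal)."""

    family_ids: list[str]
    block_ids: dict[str, list[str]]     # family_id -> subject order in block
    blocks: dict[str, np.ndarray]       # family_id -> square block
    source: str = "kinship"

    def __post_init__(self):
        for fid in self.family_ids:
            B = self.blocks[fid]
            k = len(self.block_ids[fid])
            if B.shape != (k, k):
                raise ValueError(f"block for family {fid!r} has wrong shape")
            if not np.allclose(B, B.T, atol=1e-12, rtol=0):
                raise ValueError(f"block for family {fid!r} not symmetric")

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_subjects(self) -> int:
        return sum(len(v) for v in self.block_ids.values())

    def family_of(self) -> dict[str, str]:
        return {
            sid: fid for fid in self.family_ids for sid in self.block_ids[fid]
        }

    def to_dense(self) -> RelatednessMatrix:
        """Materialize the implied full matrix (zeros between families)."""
        ids = [s for fid in self.family_ids for s in self.block_ids[fid]]
        n = len(ids)
        V = np.zeros((n, n))
        pos = 0
        for fid in self.family_ids:
            k = len(self.block_ids[fid])
            V[pos : pos + k, pos : pos + k] = self.blocks[fid]
            pos += k
        return RelatednessMatrix(ids=ids, values=V, source=self.source)


def sparsify_by_family(
    grm: RelatednessMatrix, family_of: dict[str, str]
) -> SparseClusteredGRM:
    """Zero out relatedness between members of different families.

    Within-family entries are copied unchanged; between-family entries are
    dropped (implicitly zero). Every subject in ``grm`` must appear in
    ``family_of``.
    """
    missing = [s for s in grm.ids if s not in family_of]
    if missing:
        raise KeyError(
            f"subject(s) in GRM without family assignment: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    fam_order: list[str] = []
    members: dict[str, list[str]] = {}
    for s in grm.ids:
        f = str(family_of[s])
        if f not in members:
            members[f] = []
            fam_order.append(f)
        members[f].append(s)

    blocks = {}
    for f in fam_order:
        idx = [grm.index_of(s) for s in members[f]]
        blocks[f] = grm.values[np.ix_(idx, idx)].copy()
    return SparseClusteredGRM(
        family_ids=fam_order, block_ids=members, blocks=blocks, source=grm.source
    )


def nearest_psd(block: np.ndarray) -> np.ndarray:
    """Nearest positive-semidefinite repair by clipping eigenvalues at 0."""
    w, Q = np.linalg.eigh((block + block.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return (Q * w) @ Q.T


def expand_to_observations(
    block_ids: list[str],
    block: np.ndarray,
    observations: pd.DataFrame,
) -> dict[str, np.ndarray]:
    """Expand one family's relatedness block to observation-level component
    matrices for the five random effects.

    ``observations`` needs columns subject_id, pregnancy_id, visit (one row
    per observation in this family). Returns ``{"A": K_A, "C": J_C,
    "T": J_T, "S": J_S, "E": I_E}`` where K_A carries relatedness between
    the observations' subjects (1 on and between a subject's own
    observations), J_C is all ones (shared family), J_T / J_S indicate
    shared pregnancy / subject, and I_E is the identity.
    """
    subs = observations["subject_id"].astype(str).to_numpy()
    pregs = observations["pregnancy_id"].astype(str).to_numpy()
    visits = observations["visit"].to_numpy()

    dup = pd.DataFrame({"s": subs, "v": visits}).duplicated()
    if dup.any():
        bad = [(subs[i], visits[i]) for i in np.where(dup)[0]]
        raise ValueError(f"duplicate (subject, visit) observation rows: {bad}")

    pos = {str(s): k for k, s in enumerate(block_ids)}
    unknown = [s for s in subs if s not in pos]
    if unknown:
        raise KeyError(
            f"observation subject(s) not in relatedness block: {sorted(set(unknown))}"
        )
    idx = np.array([pos[s] for s in subs])

    K_A = block[np.ix_(idx, idx)].copy()
    same_subject = subs[:, None] == subs[None, :]
    K_A[same_subject] = 1.0  # a subject is fully related to itself across visits
    m = len(subs)
    return {
        "A": K_A,
        "C": np.ones((m, m)),
        "T": (pregs[:, None] == pregs[None, :]).astype(float),
        "S": same_subject.astype(float),
        "E": np.eye(m),
    }
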