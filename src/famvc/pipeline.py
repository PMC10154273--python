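"""End-to-end fitting: table + relatedness -> variance-component fit.

Wires the two-stage workflow: complete cases and pre-residualization on
fixed-effect covariates, kinship construction or GRM intersection,
family sparsification, pregnancy-ID derivation (for T), then the ML fit.
"""

from __future__ import annotations

import logging

import pandas as pd

from .engine import FitOptions, RandomEffectDesign, VarianceComponentFit, fit_ml
from .io import intersect_with_grm
from .relatedness import (
    RelatednessMatrix,
    build_kinship_grm,
    derive_pregnancy_id,
    sparsify_by_family,
    subjects_from_frame,
)
from .residualize import CovariateSpec, practice_indicator, residualize

logger = logging.getLogger(__name__)

__all__ = ["fit_model"]


def fit_model(
    table: pd.DataFrame,
    phenotype: str,
    model: str | RandomEffectDesign = "ACE",
    *,
    grm: RelatednessMatrix | str = "kinship",
    covariates: tuple[str, ...] = ("age", "sex"),
    practice: str = "auto",
    options: FitOptions | None = None,
) -> VarianceComponentFit:
    """Fit a variance-component model to one phenotype of a long table.

    Parameters
    ----------
    table : DataFrame
        Long format, one row per (subject, visit): subject_id, family_id,
        visit, the phenotype, covariates, and (for kinship construction /
        T effects) birth_date and zygosity.
    phenotype : str
        Column to analyze.
    model : str
        Random-effect set, e.g. "ACE", "ACTE", "ACSE".
    grm : RelatednessMatrix or "kinship"
        "kinship" builds pedigree-expectation relatedness from the
        table's family/zygosity columns; a supplied matrix (e.g.
        SNP-derived) is intersected with the table's subjects.
    practice : {"auto", "on", "off"}
        Repeat-assessment dummy in the residualization; "auto" includes
        it iff any subject contributes more than one visit.

    Returns
    -------
    VarianceComponentFit
    """
    design = (
        model
        if isinstance(model, RandomEffectDesign)
        else RandomEffectDesign.from_string(model)
    )
    if practice not in ("auto", "on", "off"):
        raise ValueError(f"practice must be 'auto', 'on' or 'off', got {practice!r}")

    work = table.copy()
    if isinstance(grm, RelatednessMatrix):
        n_before = len(work)
        work, grm_mat = intersect_with_grm(work, grm)
        if len(work) != n_before:
            logger.info("intersection with GRM dropped %d row(s)",
                        n_before - len(work))
    elif grm == "kinship":
        grm_mat = None
    else:
        raise ValueError(f"grm must be 'kinship' or a RelatednessMatrix, got {grm!r}")

    if practice == "auto":
        per_subject = work.loc[work[phenotype].notna()].groupby("subject_id").size()
        include_practice = bool((per_subject > 1).any())
    else:
        include_practice = practice == "on"
    spec = CovariateSpec(covariates=tuple(covariates),
                         include_practice=include_practice)
    if include_practice and "practice" not in work.columns:
        work["practice"] = practice_indicator(work, phenotype=phenotype)

    rp = residualize(work, spec, phenotype)
    obs = work.loc[rp.values.index].copy()
    logger.info(
        "residualized %s: n_obs=%d dropped=%d df_used=%d practice=%s",
        phenotype, rp.n_obs, rp.n_dropped, rp.df_used, include_practice,
    )

    subjects = subjects_from_frame(obs)
    if grm_mat is None:
        grm_mat = build_kinship_grm(subjects)
    else:
        grm_mat = grm_mat.subset(
            [s for s in grm_mat.ids
             if s in set(obs["subject_id"].astype(str))]
        )

    have_birth_dates = all(s.birth_date is not None for s in subjects)
    if "T" in design.effects and not have_birth_dates:
        raise ValueError("T effect requires birth_date for every subject")
    preg = derive_pregnancy_id(
        subjects, on_missing_birth_date="error" if have_birth_dates else "own"
    )
    obs["pregnancy_id"] = obs["subject_id"].astype(str).map(preg)

    fam_of = dict(zip(obs["subject_id"].astype(str), obs["family_id"].astype(str)))
    sgrm = sparsify_by_family(grm_mat, fam_of)
    logger.info(
        "sparse GRM: %d subjects in %d families (%s-derived)",
        sgrm.n_subjects, sgrm.n_families, sgrm.source,
    )

    fit = fit_ml(rp, obs, sgrm, design, options=options, phenotype=phenotype)
    logger.info(
        "fit %s on %s: loglik=%.4f AIC=%.4f fractions=%s",
        fit.model, phenotype, fit.log_likelihood, fit.aic,
        {e: round(v, 4) for e, v in fit.fractions.items()},
    )
    return fit
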