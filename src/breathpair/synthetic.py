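"""Synthetic paired multi-block cohort generator.

Each feature value is built on a latent scale as

    baseline + visit effect + subject effect + residual

where the subject effect and the residual each mix one block-shared factor
(loading sqrt(rho)) with an independent per-feature term (loading
sqrt(1 - rho)), so the latent correlation between any two features of a block
equals rho — one parameter reproducing the cross-sensor redundancy seen in
real e-nose arrays. Lognormal-family blocks exponentiate the latent value, so
treatment effects are multiplicative and values are strictly positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort
from .config import SyntheticConfig

__all__ = ["generate_cohort", "apply_missingness", "simulate"]


def _subject_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw one fully-observed cohort from ``config`` (bit-reproducible).

    Returns ``n_subjects * len(visits)`` samples per block, ordered
    subject-major then visit in config order.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    subjects = _subject_ids(config.n_subjects)
    index = pd.MultiIndex.from_product(
        [subjects, list(config.visits)], names=["subject", "visit"]
    )
    n_sub, n_vis = config.n_subjects, len(config.visits)
    n_samples = n_sub * n_vis

    blocks: dict[str, pd.DataFrame] = {}
    masks: dict[str, pd.DataFrame] = {}
    for spec in config.blocks:
        p = spec.n_features
        baseline = spec.baseline_array()
        sig_s = spec.sigma_s_array()
        sig_e = spec.sigma_e_array()
        shared, indep = np.sqrt(spec.rho), np.sqrt(1.0 - spec.rho)

        subj_factor = rng.standard_normal(n_sub)           # block-shared, per subject
        subj_noise = rng.standard_normal((n_sub, p))        # per subject x feature
        samp_factor = rng.standard_normal(n_samples)        # block-shared, per sample
        samp_noise = rng.standard_normal((n_samples, p))    # per sample x feature

        subject_effect = sig_s * (shared * subj_factor[:, None] + indep * subj_noise)
        residual = sig_e * (shared * samp_factor[:, None] + indep * samp_noise)

        deltas = np.zeros((n_vis, p))
        for j, feat in enumerate(spec.features):
            for v, visit in enumerate(config.visits):
                deltas[v, j] = config.effects.get((spec.name, feat, visit), 0.0)

        latent = (
            baseline[None, :]
            + np.repeat(subject_effect, n_vis, axis=0)
            + np.tile(deltas, (n_sub, 1))
            + residual
        )
        values = np.exp(latent) if spec.family == "positive-lognormal" else latent
        blocks[spec.name] = pd.DataFrame(values, index=index, columns=list(spec.features))
        masks[spec.name] = pd.DataFrame(True, index=index, columns=list(spec.features))

    return Cohort(
        blocks=blocks,
        masks=masks,
        provenance={"generator": "breathpair.synthetic", "seed": config.seed},
    )


def apply_missingness(cohort: Cohort, config: SyntheticConfig) -> Cohort:
    """Flag cells unavailable, independently per cell at each block's rate.

    Values are left untouched; only masks change. Seeded from
    ``config.seed`` on a stream separate from :func:`generate_cohort`, so the
    same config yields the same generated values and the same missing pattern.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    masks = {name: mask.copy() for name, mask in cohort.masks.items()}
    for block, rate in config.missingness.items():
        if block not in cohort.blocks:
            raise KeyError(f"missingness refers to unknown block {block!r}")
        if rate == 0.0:
            continue
        shape = cohort.blocks[block].shape
        drop = rng.random(shape) < rate
        masks[block] = masks[block] & pd.DataFrame(
            ~drop, index=cohort.blocks[block].index, columns=cohort.blocks[block].columns
        )
    return Cohort(
        blocks={name: df.copy() for name, df in cohort.blocks.items()},
        masks=masks,
        provenance=dict(cohort.provenance),
    )


def simulate(config: SyntheticConfig) -> Cohort:
    """Generate a cohort and apply the configured missingness."""
    return apply_missingness(generate_cohort(config), config)
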