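"""Centered, unit-norm expression pattern vectors on the hypersphere.

Each sample's panel-restricted expression profile is centered by the cohort
mean vector and scaled to unit Euclidean norm, so that downstream analyses
see relative expression *patterns* rather than absolute levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FPKM_UQ, LOG2P1, ExpressionMatrix


class ScaleError(ValueError):
    """Operation applied to a matrix on the wrong value scale."""


class DegenerateSampleError(ValueError):
    """A sample coincides with the cohort mean; its pattern is undefined."""


@dataclass
class PatternVectors:
    """Per-sample unit vectors on the (n-1)-sphere for one panel."""

    sample_ids: list[str]
    vectors: np.ndarray  # samples x n, rows unit-norm
    panel_name: str
    n: int
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (len(self.sample_ids), self.n):
            raise ValueError("vectors shape does not match sample_ids / n")
        if self.gene_ids is None:
            self.gene_ids = [f"g{i + 1}" for i in range(self.n)]
        if len(self.gene_ids) != self.n:
            raise ValueError("gene_ids length must equal n")
        norms = np.linalg.norm(self.vectors, axis=1)
        if self.vectors.size and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("pattern vector rows must have unit norm")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: list[str]) -> np.ndarray:
        """Raw rows for the given samples (no re-centering)."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        return self.vectors[[idx[s] for s in sample_ids]]


def invert_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map log2(x+1) values back to raw scale: v -> 2**v - 1."""
    if m.scale != LOG2P1:
        raise ScaleError(f"matrix scale is {m.scale!r}; refusing to invert twice")
    return ExpressionMatrix(
        sample_ids=list(m.sample_ids),
        gene_ids=list(m.gene_ids),
        values=np.exp2(m.values) - 1.0,
        scale=FPKM_UQ,
    )


def center_and_project(m: ExpressionMatrix, panel_name: str = "") -> PatternVectors:
    """Center each sample vector by the cohort mean and scale to unit norm.

    The mean is the unweighted arithmetic mean over the samples present in
    ``m`` — callers performing subset re-analysis must pass the subset so the
    centering is recomputed within it.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples to center")
    if m.n_genes < 1:
        raise ValueError("need at least 1 gene")
    centered = m.values - m.values.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    bad = np.nonzero(norms < 1e-12)[0]
    if bad.size:
        names = [m.sample_ids[i] for i in bad[:5]]
        raise DegenerateSampleError(
            f"samples identical to the cohort mean (zero pattern): {names}"
        )
    return PatternVectors(
        sample_ids=list(m.sample_ids),
        vectors=centered / norms[:, None],
        panel_name=panel_name or "unnamed",
        n=m.n_genes,
        gene_ids=list(m.gene_ids),
    )


def pattern_vectors_for_panel(
    m: ExpressionMatrix, panel, *, work_on_log_scale: bool = False, allow_missing: bool = False
) -> PatternVectors:
    """Panel subset -> (optional) inverse log transform -> center & project.

    ``work_on_log_scale`` keeps log2(x+1) values as the vector coordinates
    instead of inverting to the raw scale first.
    """
    from .io import subset_to_panel

    sub = subset_to_panel(m, panel, allow_missing=allow_missing)
    if not work_on_log_scale and sub.scale == LOG2P1:
        sub = invert_log_transform(sub)
    return center_and_project(sub, panel_name=panel.name)
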