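"""Model-based reference-gene stability screening (NormFinder-style).

An on-slide reference transcript for normalizing smFISH counts must be
stably expressed across samples and disease groups.  Given a log2-scale
genes x samples matrix, this module scores each candidate gene with a
model-based variance decomposition: sample (array) effects are absorbed
by two-way centering within each group; a gene's intra-group variance is
estimated from the within-group residuals with a correction for the bias
introduced by centering over a finite gene ensemble; its inter-group
variance comes from the spread of its centered group effects after
subtracting the sampling contribution.  The stability value combines the
shrunken group effect with its standard error — lower is more stable.

Model (log scale), gene i, group g, sample j:

    y_igj = alpha_ig + beta_gj + eps_igj,   Var(eps_igj) = sigma2_ig

With r_igj the two-way-centered residuals and m_ig = sum_j r^2 / (n_g - 1),
E[m_ig] = sigma2_ig (I-2)/I + mean_i(sigma2_ig)/I for I genes, giving the
bias-corrected estimate

    sigma2_ig = I/(I-2) * (m_ig - mean_i(m_ig)/(I-1)),  floored at 0.

Group effects d_ig (gene-centered within group, then centered over
groups) are modelled as draws from a zero-mean ensemble prior with
variance gamma2_g, estimated per group across the candidate genes:

    gamma2_g = max( sum_i d_ig^2/(I-1) - mean_i(eta_ig), 0 )

where eta_ig is the sampling variance of d_ig implied by the intra-group
variances (eta_ig = (1-1/G)^2 sigma2_ig/n_g + (1/G^2) sum_{h!=g}
sigma2_ih/n_h).  The stability value combines the shrunken group effect
with its standard error,

    rho_i = mean_g( |d_ig * lambda_ig| + SE_ig ),
    lambda_ig = gamma2_g / (gamma2_g + eta_ig),
    SE_ig = sqrt( gamma2_g * eta_ig / (gamma2_g + eta_ig) ),

so a gene with large intra-group noise is penalized through its SE even
when its apparent group effect shrinks to zero.  With a single group the
score reduces to the per-gene SD of the sample-centered residuals (same
bias-corrected variance estimate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-scale expression with per-sample group labels."""

    values: np.ndarray
    gene_names: list[str]
    sample_names: list[str]
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a genes x samples matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_names) != n_genes:
            raise ValueError("gene_names length does not match matrix rows")
        if len(self.sample_names) != n_samples:
            raise ValueError("sample_names length does not match matrix columns")
        if self.group_labels is not None and len(self.group_labels) != n_samples:
            raise ValueError("group_labels length does not match matrix columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_groups(self) -> int:
        if self.group_labels is None:
            return 1
        return len(set(self.group_labels))

    @classmethod
    def from_linear(cls, values: np.ndarray, gene_names, sample_names,
                    group_labels=None, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Build from linear-scale values: log2(x + pseudocount)."""
        return cls(np.log2(np.asarray(values, dtype=np.float64) + pseudocount),
                   list(gene_names), list(sample_names),
                   list(group_labels) if group_labels is not None else None)

    @classmethod
    def read_tsv(cls, path, sep: str = "\t") -> "ExpressionMatrix":
        """Read a delimited matrix: header row = sample names, second header
        row (index 'group') = group labels, then one row per gene."""
        frame = pd.read_csv(path, sep=sep, index_col=0)
        if len(frame) and str(frame.index[0]).lower() == "group":
            groups = [str(v) for v in frame.iloc[0]]
            frame = frame.iloc[1:].astype(float)
        else:
            groups = None
        return cls(frame.to_numpy(dtype=np.float64),
                   [str(i) for i in frame.index],
                   [str(c) for c in frame.columns], groups)

    def write_tsv(self, path, sep: str = "\t") -> None:
        frame = pd.DataFrame(self.values, index=self.gene_names,
                             columns=self.sample_names)
        if self.group_labels is not None:
            frame = pd.concat([
                pd.DataFrame([self.group_labels], index=["group"],
                             columns=self.sample_names),
                frame,
            ])
        frame.to_csv(path, sep=sep)


@dataclass
class StabilityResult:
    """Per-gene stability values (lower = more stable) and variance components."""

    gene_names: list[str]
    stability: np.ndarray                  # (genes,)
    intra_group_var: np.ndarray            # (genes, groups)
    inter_group_var: np.ndarray            # (genes,)
    group_names: list[str]
    mode: str                              # "grouped" | "single"
    rank: list[str] = field(default_factory=list)  # gene names, most stable first

    def __post_init__(self) -> None:
        if not self.rank:
            order = sorted(range(len(self.gene_names)),
                           key=lambda i: (self.stability[i], self.gene_names[i]))
            self.rank = [self.gene_names[i] for i in order]

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "gene": self.gene_names,
            "stability": self.stability,
            "inter_group_var": self.inter_group_var,
        })
        for g, name in enumerate(self.group_names):
            frame[f"intra_var_{name}"] = self.intra_group_var[:, g]
        frame["rank"] = [self.rank.index(g) + 1 for g in self.gene_names]
        return frame.sort_values("rank", ignore_index=True)


def _corrected_intra_var(residuals: np.ndarray, n_samples: int) -> np.ndarray:
    """Ensemble-bias-corrected within-group variances from centered residuals."""
    I = residuals.shape[0]
    m = (residuals ** 2).sum(axis=1) / (n_samples - 1)
    sigma2 = I / (I - 2) * (m - m.mean() / (I - 1))
    return np.maximum(sigma2, 0.0)


def normfinder_stability(matrix: ExpressionMatrix,
                         grouped: bool | None = None) -> StabilityResult:
    """Score reference-gene stability by model-based variance decomposition.

    ``grouped=None`` selects grouped mode when the matrix carries >= 2
    groups.  Grouped mode requires >= 2 samples per group; both modes
    require >= 3 genes (the ensemble bias correction needs I - 2 > 0).
    """
    y = matrix.values
    I, n = y.shape
    if I < 3:
        raise ValueError("stability screening needs at least 3 genes")
    if grouped is None:
        grouped = matrix.n_groups >= 2
    if grouped and matrix.n_groups < 2:
        raise ValueError("grouped mode requires >= 2 groups")

    if not grouped:
        centered = y - y.mean(axis=0, keepdims=True)          # remove sample effects
        centered -= centered.mean(axis=1, keepdims=True)      # remove gene means
        if n < 2:
            raise ValueError("need >= 2 samples")
        sigma2 = _corrected_intra_var(centered, n)
        return StabilityResult(
            gene_names=list(matrix.gene_names),
            stability=np.sqrt(sigma2),
            intra_group_var=sigma2[:, None],
            inter_group_var=np.zeros(I),
            group_names=["all"],
            mode="single",
        )

    labels = matrix.group_labels
    group_names = sorted(set(labels))
    G = len(group_names)
    sigma2 = np.empty((I, G))
    gene_effect = np.empty((I, G))  # a_ig: gene effect within group, centered over genes
    n_g = np.empty(G)
    for g, name in enumerate(group_names):
        cols = [j for j, lab in enumerate(labels) if lab == name]
        if len(cols) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
        n_g[g] = len(cols)
        block = y[:, cols]
        gene_mean = block.mean(axis=1)
        sample_mean = block.mean(axis=0)
        grand = block.mean()
        resid = block - gene_mean[:, None] - sample_mean[None, :] + grand
        sigma2[:, g] = _corrected_intra_var(resid, len(cols))
        gene_effect[:, g] = gene_mean - gene_mean.mean()

    d = gene_effect - gene_effect.mean(axis=1, keepdims=True)  # centered over groups
    # sampling variance of d_ig implied by the intra-group variances
    noise = sigma2 / n_g[None, :]
    eta = ((1 - 1 / G) ** 2) * noise + (noise.sum(axis=1, keepdims=True) - noise) / G**2
    # ensemble prior variance of the group effects, per group
    gamma2 = np.maximum((d ** 2).sum(axis=0) / (I - 1) - eta.mean(axis=0), 0.0)
    denom = gamma2[None, :] + eta
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(denom > 0, gamma2[None, :] / denom, 0.0)
        se = np.sqrt(np.where(denom > 0, gamma2[None, :] * eta / denom, 0.0))
    stability = (np.abs(d * lam) + se).mean(axis=1)

    return StabilityResult(
        gene_names=list(matrix.gene_names),
        stability=stability,
        intra_group_var=sigma2,
        inter_group_var=np.maximum((d ** 2).sum(axis=1) / (G - 1)
                                   - eta.mean(axis=1), 0.0),
        group_names=group_names,
        mode="grouped",
    )


def rank_reference_genes(result: StabilityResult, top_k: int | None = None) -> list[str]:
    """Genes ordered by ascending stability, ties broken by gene name."""
    ranked = list(result.rank)
    if top_k is None:
        return ranked
    if top_k > len(ranked):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(ranked)} available genes; truncating",
            stacklevel=2)
        top_k = len(ranked)
    return ranked[:top_k]
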