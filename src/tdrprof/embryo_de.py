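"""Single-embryo mRNA-seq differential expression and gene-group analysis.

The DE rule is deliberately simple: per gene, an unpaired two-tailed t-test
on per-embryo TPM between conditions, with a call of "up" when
log2 fold change > 1 and p <= 0.01, "down" when log2 fold change < -1 and
p <= 0.01, otherwise "ns". Fold changes use a pseudocount (default 1 TPM)
because single embryos contain genuine zeros. No multiple-testing
correction is applied by default (the cutoff is on the raw p); BH-adjusted
values can be added with ``bh=True``.

Coordinated regulation of gene families (canonical histones, fbxb F-box
genes, hsp heat-shock genes, rpl/rps ribosomal proteins) is read off the
cumulative distribution of per-gene log2 fold changes: the group's ECDF is
compared with that of all remaining genes by a two-sample KS test together
with the median shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stattests import bh_adjust, ks_two_sample

__all__ = [
    "ExpressionMatrix",
    "GeneGroup",
    "tpm_normalize",
    "filter_expressed",
    "de_test",
    "resolve_groups",
    "group_cdf_analysis",
]

TPM_TOTAL = 1e6
DEFAULT_PSEUDOCOUNT = 1.0  # TPM
DE_LOG2FC_CUTOFF = 1.0
DE_P_CUTOFF = 0.01


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample condition labels."""

    values: pd.DataFrame  # index = gene_ids, columns = sample_ids
    condition: dict[str, str]
    unit: str = "counts"  # "counts" | "TPM"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.condition)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        if self.unit not in ("counts", "TPM", "TPM(filtered)"):
            raise ValueError(f"unit must be 'counts' or 'TPM', got {self.unit!r}")
        if self.unit == "TPM":
            sums = self.values.sum(axis=0)
            bad = sums[(sums - TPM_TOTAL).abs() > 1e-3 * TPM_TOTAL]
            if not bad.empty:
                raise ValueError(
                    f"TPM columns must sum to 1e6; offenders: {list(bad.index)}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition[s] == condition]


def tpm_normalize(
    mat: ExpressionMatrix, gene_lengths: Mapping[str, float] | pd.Series
) -> ExpressionMatrix:
    """Convert a count matrix to TPM: length-normalize, then scale to 1e6."""
    if mat.unit != "counts":
        raise ValueError("tpm_normalize expects a counts matrix")
    lengths = pd.Series(gene_lengths, dtype=float).reindex(mat.values.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:5])
        raise ValueError(f"genes without a length: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = mat.values.div(lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * TPM_TOTAL
    return ExpressionMatrix(
        values=tpm, condition=dict(mat.condition), unit="TPM", meta=dict(mat.meta)
    )


def filter_expressed(
    mat: ExpressionMatrix,
    min_mean_tpm: float = 1.0,
    min_fraction_samples: float = 0.0,
) -> ExpressionMatrix:
    """Keep genes detected above a TPM floor.

    A gene passes if its mean TPM reaches ``min_mean_tpm`` in at least one
    condition, and (optionally) it is non-zero in at least
    ``min_fraction_samples`` of all samples. The rule applied is recorded in
    the output metadata.
    """
    if mat.unit != "TPM":
        raise ValueError("filter_expressed expects a TPM matrix")
    conditions = sorted(set(mat.condition.values()))
    passes = pd.Series(False, index=mat.values.index)
    for cond in conditions:
        cols = mat.samples_in(cond)
        passes |= mat.values[cols].mean(axis=1) >= min_mean_tpm
    if min_fraction_samples > 0:
        frac_nonzero = (mat.values > 0).mean(axis=1)
        passes &= frac_nonzero >= min_fraction_samples
    if not passes.any():
        raise ValueError("expression filter removed every gene")
    meta = dict(mat.meta)
    meta["expression_filter"] = (
        f"mean TPM >= {min_mean_tpm} in >= 1 condition"
        + (
            f"; non-zero in >= {min_fraction_samples:.0%} of samples"
            if min_fraction_samples > 0
            else ""
        )
    )
    # subsetting genes breaks the column-sum invariant on purpose: values
    # remain on the TPM scale of the full library
    return ExpressionMatrix(
        values=mat.values.loc[passes],
        condition=dict(mat.condition),
        unit="TPM(filtered)",
        meta=meta,
    )


def _vectorized_t(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise unpaired two-tailed t (pooled variance) on 2-d arrays."""
    from scipy import stats as sps

    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * sps.t.sf(np.abs(t), df)
    degenerate = sp2 == 0
    equal_means = m1 == m2
    t = np.where(degenerate, np.where(equal_means, 0.0, np.inf), t)
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    return t, p


def de_test(
    mat: ExpressionMatrix,
    condition_a: str,
    condition_b: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log_transform: bool = False,
    bh: bool = False,
    log2fc_cutoff: float = DE_LOG2FC_CUTOFF,
    p_cutoff: float = DE_P_CUTOFF,
) -> pd.DataFrame:
    """Per-gene differential expression of condition_b versus condition_a.

    Returns a frame with gene_id, mean_a, mean_b, log2fc
    (= log2((mean_b + eps)/(mean_a + eps))), p from an unpaired two-tailed
    t-test on per-sample TPM (on log2(TPM + eps) if ``log_transform``), and
    the call. Swapping the conditions negates log2fc and flips up <-> down.
    """
    if not mat.unit.startswith("TPM"):
        raise ValueError("de_test expects TPM values")
    cols_a = mat.samples_in(condition_a)
    cols_b = mat.samples_in(condition_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each condition needs at least 2 replicates")
    a = mat.values[cols_a].to_numpy(float)
    b = mat.values[cols_b].to_numpy(float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    if log_transform:
        t, p = _vectorized_t(np.log2(a + pseudocount), np.log2(b + pseudocount))
    else:
        t, p = _vectorized_t(a, b)
    out = pd.DataFrame(
        {
            "gene_id": mat.values.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "t": t,
            "p": p,
        }
    ).set_index("gene_id")
    significant = out["p"] <= p_cutoff
    out["call"] = "ns"
    out.loc[significant & (out["log2fc"] > log2fc_cutoff), "call"] = "up"
    out.loc[significant & (out["log2fc"] < -log2fc_cutoff), "call"] = "down"
    if bh:
        out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    out.attrs["pseudocount"] = pseudocount
    out.attrs["conditions"] = (condition_a, condition_b)
    out.attrs["log_transform"] = log_transform
    return out


@dataclass
class GeneGroup:
    name: str
    members: list[str]

    def __post_init__(self) -> None:
        self.members = sorted(set(self.members))


def _locus_stem(gene_name: str) -> str:
    """The locus-name stem before the first hyphen ('hsp-16.2' -> 'hsp')."""
    return gene_name.split("-", 1)[0]


def resolve_groups(
    gene_names: Iterable[str],
    prefix_rules: Mapping[str, str] | None = None,
    explicit_lists: Mapping[str, Sequence[str]] | None = None,
) -> list[GeneGroup]:
    """Build gene groups from locus-name stems and/or curated lists.

    ``prefix_rules`` maps a group name to a stem (e.g. {"hsp": "hsp"}); a
    gene matches only when the part before its first hyphen equals the stem,
    so "hsph-1" is not captured by the "hsp" rule. Curated lists (e.g. the
    canonical his-* histones, excluding H3.3 variants) are intersected with
    the supplied gene names.
    """
    names = list(gene_names)
    groups: list[GeneGroup] = []
    for group_name, stem in (prefix_rules or {}).items():
        members = [g for g in names if _locus_stem(g) == stem]
        groups.append(GeneGroup(group_name, members))
    available = set(names)
    for group_name, members in (explicit_lists or {}).items():
        groups.append(GeneGroup(group_name, [g for g in members if g in available]))
    return groups


def group_cdf_analysis(
    de_results: pd.DataFrame,
    groups: Sequence[GeneGroup],
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Coordinated-shift report per gene group.

    For each group, the distribution of member log2 fold changes is compared
    with that of all remaining genes: two-sample KS test, median shift
    (member median minus background median), and a direction label. Groups
    with fewer than ``min_group_size`` expressed members are skipped with a
    warning; a group swallowing every gene leaves no background and is an
    error.
    """
    fc = de_results["log2fc"]
    rows = []
    for group in groups:
        members = fc.index.intersection(group.members)
        if len(members) < min_group_size:
            warnings.warn(
                f"group {group.name!r}: only {len(members)} expressed members; skipped"
            )
            continue
        background = fc.index.difference(members)
        if len(background) == 0:
            raise ValueError(f"group {group.name!r} covers all genes: no background")
        member_fc = fc.loc[members].to_numpy()
        background_fc = fc.loc[background].to_numpy()
        ks = ks_two_sample(member_fc, background_fc)
        shift = float(np.median(member_fc) - np.median(background_fc))
        rows.append(
            {
                "group": group.name,
                "n_members": len(members),
                "n_background": len(background),
                "median_shift": shift,
                "ks_D": ks.statistic,
                "ks_p": ks.p_value,
                "direction": "down" if shift < 0 else ("up" if shift > 0 else "none"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "n_members",
            "n_background",
            "median_shift",
            "ks_D",
            "ks_p",
            "direction",
        ],
    )
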