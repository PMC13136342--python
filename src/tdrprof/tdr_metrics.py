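"""tDR-specific summaries over tRNA-assigned reads.

Four views of the tRNA-mapping fraction of a library:

* length x first-nucleotide matrices (18-40 nt rows, A/C/G/T columns),
* 5'/3' arm fractions, with the mature tRNA split at the anticodon,
* per-nucleotide read depth along each mature tRNA,
* the >30 / <=30 nt split per isodecoder, the signature separating
  tRNA-halves from shorter fragments.

Arm semantics: the 5' arm is everything before the anticodon, the 3' arm
everything after it; the three anticodon positions belong to neither. A read
is assigned to the arm holding the majority of its aligned positions, with
an exact tie going to 5'. Antisense tRNA alignments are never part of arm
fractions; they are tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import TrnaModel
from .classify import Alignment, ReadAssignment, ReadRecord

__all__ = [
    "ArmSummary",
    "TdrProfile",
    "assign_arm",
    "arm_summary",
    "length_first_nt",
    "per_nt_coverage",
    "long_short_split",
    "isoacceptor_rollup",
    "build_profiles",
]

LENGTH_RANGE = range(18, 41)
NT_COLUMNS = ("A", "C", "G", "T")
HALF_THRESHOLD = 30  # reads of exactly 30 nt count as "short"


@dataclass
class ArmSummary:
    five_prime_count: float = 0.0
    three_prime_count: float = 0.0
    antisense_count: float = 0.0

    @property
    def five_prime_pct(self) -> float:
        total = self.five_prime_count + self.three_prime_count
        if total == 0:
            return float("nan")
        return 100.0 * self.five_prime_count / total

    @property
    def three_prime_pct(self) -> float:
        pct5 = self.five_prime_pct
        return float("nan") if np.isnan(pct5) else 100.0 - pct5


def assign_arm(aln: Alignment, model: TrnaModel) -> str:
    """Assign a sense tRNA alignment to the 5' or 3' arm ("5p"/"3p")."""
    if aln.antisense:
        raise ValueError("antisense tRNA alignments carry no arm label")
    ac = model.anticodon_start
    length = len(model.mature_seq)
    ov5 = max(0, min(aln.target_end, ac) - max(aln.target_start, 0))
    ov3 = max(0, min(aln.target_end, length) - max(aln.target_start, ac + 3))
    return "5p" if ov5 >= ov3 else "3p"


def arm_summary(
    assignments: Iterable[ReadAssignment],
    models: Mapping[str, TrnaModel],
    feature_id: str | None = None,
) -> ArmSummary:
    """Tally weighted 5'/3' arm counts, optionally for one tRNA feature."""
    out = ArmSummary()
    for a in assignments:
        if a.cls != "tRNA" or a.alignment is None:
            continue
        if feature_id is not None and a.feature_id != feature_id:
            continue
        if a.alignment.antisense:
            out.antisense_count += a.weight
            continue
        arm = assign_arm(a.alignment, models[a.feature_id])
        if arm == "5p":
            out.five_prime_count += a.weight
        else:
            out.three_prime_count += a.weight
    return out


def length_first_nt(
    assignments: Iterable[ReadAssignment],
    reads_by_id: Mapping[str, ReadRecord],
    cls: str = "tRNA",
) -> tuple[pd.DataFrame, float]:
    """Length x first-nucleotide matrix of weighted counts for one class.

    Returns (matrix, excluded_weight); reads starting with N (or outside the
    18-40 nt window) contribute to the excluded weight instead of a cell.
    """
    mat = pd.DataFrame(
        0.0, index=pd.Index(LENGTH_RANGE, name="length"), columns=list(NT_COLUMNS)
    )
    excluded = 0.0
    for a in assignments:
        if a.cls != cls:
            continue
        read = reads_by_id[a.read_id]
        if read.first_nt not in NT_COLUMNS or read.length not in mat.index:
            excluded += a.weight
            continue
        mat.loc[read.length, read.first_nt] += a.weight
    return mat, excluded


def per_nt_coverage(
    assignments: Iterable[ReadAssignment],
    model: TrnaModel,
) -> np.ndarray:
    """Sense read depth per position of one mature tRNA (weighted)."""
    depth = np.zeros(len(model.mature_seq))
    for a in assignments:
        aln = a.alignment
        if a.cls != "tRNA" or aln is None or aln.antisense:
            continue
        if a.feature_id != model.name:
            continue
        depth[aln.target_start : aln.target_end] += a.weight
    return depth


def long_short_split(
    assignments: Iterable[ReadAssignment],
    reads_by_id: Mapping[str, ReadRecord],
    threshold: int = HALF_THRESHOLD,
) -> pd.DataFrame:
    """Per-isodecoder weighted counts of reads > threshold vs <= threshold nt.

    With the default threshold of 30 nt the long bin captures tRNA-halves
    and the short bin shorter fragments; a 30 nt read is "short".
    """
    if threshold < 18:
        raise ValueError("threshold below the smallest retained read length")
    rows: dict[str, dict[str, float]] = {}
    for a in assignments:
        if a.cls != "tRNA":
            continue
        entry = rows.setdefault(a.feature_id, {"long_count": 0.0, "short_count": 0.0})
        if reads_by_id[a.read_id].length > threshold:
            entry["long_count"] += a.weight
        else:
            entry["short_count"] += a.weight
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "trna"
    return df


@dataclass
class TdrProfile:
    """Everything computed for one tRNA feature."""

    trna: TrnaModel
    depth: np.ndarray
    arm: ArmSummary
    lf_matrix: pd.DataFrame
    long_count: float
    short_count: float

    @property
    def total(self) -> float:
        return self.long_count + self.short_count


def build_profiles(
    assignments: Sequence[ReadAssignment],
    reads_by_id: Mapping[str, ReadRecord],
    models: Mapping[str, TrnaModel],
    threshold: int = HALF_THRESHOLD,
) -> dict[str, TdrProfile]:
    """Assemble a TdrProfile per tRNA feature present in the assignments."""
    split = long_short_split(assignments, reads_by_id, threshold)
    profiles: dict[str, TdrProfile] = {}
    for name in split.index:
        model = models[name]
        per_feature = [a for a in assignments if a.feature_id == name]
        lf, _ = length_first_nt(per_feature, reads_by_id, cls="tRNA")
        profiles[name] = TdrProfile(
            trna=model,
            depth=per_nt_coverage(per_feature, model),
            arm=arm_summary(per_feature, models),
            lf_matrix=lf,
            long_count=float(split.loc[name, "long_count"]),
            short_count=float(split.loc[name, "short_count"]),
        )
    return profiles


def isoacceptor_rollup(
    profiles: Mapping[str, TdrProfile]
) -> dict[str, dict]:
    """Sum isodecoder profiles into per-isoacceptor aggregates.

    Depth vectors are 5'-anchored; shorter isodecoders are padded with
    zeros at the 3' end before element-wise summation.
    """
    groups: dict[str, list[TdrProfile]] = {}
    for prof in profiles.values():
        groups.setdefault(prof.trna.isoacceptor_id, []).append(prof)
    out: dict[str, dict] = {}
    for iso, members in groups.items():
        max_len = max(len(p.depth) for p in members)
        depth = np.zeros(max_len)
        arm = ArmSummary()
        long_count = short_count = 0.0
        lf = None
        for p in members:
            depth[: len(p.depth)] += p.depth
            arm.five_prime_count += p.arm.five_prime_count
            arm.three_prime_count += p.arm.three_prime_count
            arm.antisense_count += p.arm.antisense_count
            long_count += p.long_count
            short_count += p.short_count
            lf = p.lf_matrix if lf is None else lf + p.lf_matrix
        out[iso] = {
            "depth": depth,
            "arm": arm,
            "long_count": long_count,
            "short_count": short_count,
            "lf_matrix": lf,
            "n_isodecoders": len(members),
        }
    return out
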