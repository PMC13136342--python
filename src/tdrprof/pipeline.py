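"""End-to-end orchestration: classify -> tDR metrics -> normalization -> stats.

:func:`run_pipeline` consumes a :class:`RunConfig` (or YAML file) describing
the annotation bundle, a sample sheet of small-RNA FASTQ files with
condition labels, optional expression tables for the embryo arm, and
options. It emits per-panel TSV tables (class percentages, arm fractions,
length x first-nucleotide, coverage profiles, long/short splits, 22G
reports, DE + group reports) plus a JSON run manifest.

The normalization denominator is explicit in every report header: "reads
per million" can be taken over total genome-mapping reads, over genome
reads minus rRNA reads (which protects tDR comparisons against swings in
the rRNA degradation background), or over a single class total.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotations import AnnotationBundle, load_bundle
from .classify import (
    ClassCountTable,
    ReadRecord,
    extract_22g,
    read_fastq,
    sequential_classify,
    size_select,
    tabulate,
    trim_adapter,
)
from .embryo_de import (
    ExpressionMatrix,
    de_test,
    filter_expressed,
    group_cdf_analysis,
    resolve_groups,
    tpm_normalize,
)
from .stattests import bh_adjust, mann_whitney_two_sided, welch_t
from .tdr_metrics import arm_summary, build_profiles, length_first_nt

logger = logging.getLogger("tdrprof")

__all__ = ["RunConfig", "SmallRnaSample", "normalize_counts", "run_pipeline"]

DENOMINATORS = ("total_genome", "genome_minus_rRNA")


@dataclass
class SmallRnaSample:
    sample_id: str
    condition: str
    fastq: str


@dataclass
class RunConfig:
    bundle: str | AnnotationBundle
    outdir: str
    smallrna_samples: list[SmallRnaSample] = field(default_factory=list)
    expression_counts: str | None = None  # genes x samples TSV
    gene_lengths: str | None = None  # gene_id<TAB>length TSV
    expression_conditions: dict[str, str] = field(default_factory=dict)
    de_conditions: tuple[str, str] | None = None
    group_prefixes: dict[str, str] = field(default_factory=dict)
    group_lists: dict[str, list[str]] = field(default_factory=dict)
    adapter: str | None = None
    class_order: tuple[str, ...] = ("rRNA", "miRNA", "tRNA", "piRNA")
    max_mismatch: int = 0
    min_len: int = 18
    max_len: int = 40
    denominator: str = "genome_minus_rRNA"
    g22_genes: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def resolve(p):
            return str(base / p) if p else p

        samples = [
            SmallRnaSample(s["sample_id"], s["condition"], resolve(s["fastq"]))
            for s in raw.get("smallrna_samples", [])
        ]
        return cls(
            bundle=resolve(raw["bundle"]),
            outdir=resolve(raw["outdir"]),
            smallrna_samples=samples,
            expression_counts=resolve(raw.get("expression_counts")),
            gene_lengths=resolve(raw.get("gene_lengths")),
            expression_conditions=raw.get("expression_conditions", {}),
            de_conditions=tuple(raw["de_conditions"]) if raw.get("de_conditions") else None,
            group_prefixes=raw.get("group_prefixes", {}),
            group_lists=raw.get("group_lists", {}),
            adapter=raw.get("adapter"),
            class_order=tuple(raw.get("class_order", ("rRNA", "miRNA", "tRNA", "piRNA"))),
            max_mismatch=int(raw.get("max_mismatch", 0)),
            min_len=int(raw.get("min_len", 18)),
            max_len=int(raw.get("max_len", 40)),
            denominator=raw.get("denominator", "genome_minus_rRNA"),
            g22_genes=tuple(raw.get("g22_genes", ())),
            seed=int(raw.get("seed", 0)),
        )

    def validate(self) -> None:
        if isinstance(self.bundle, str) and not Path(self.bundle).exists():
            raise FileNotFoundError(f"bundle manifest not found: {self.bundle}")
        for s in self.smallrna_samples:
            if not Path(s.fastq).exists():
                raise FileNotFoundError(f"sample {s.sample_id}: missing {s.fastq}")
        for p in (self.expression_counts, self.gene_lengths):
            if p and not Path(p).exists():
                raise FileNotFoundError(f"missing input file: {p}")
        if not (
            self.denominator in DENOMINATORS
            or self.denominator.startswith("class:")
        ):
            raise ValueError(f"unknown denominator {self.denominator!r}")


def normalize_counts(table: ClassCountTable, denominator: str) -> pd.DataFrame:
    """Reads-per-million table for one sample under an explicit denominator.

    ``denominator`` is "total_genome", "genome_minus_rRNA", or
    "class:<name>" (e.g. "class:tRNA"). Switching the denominator rescales
    every feature of the sample by one common factor.
    """
    denom = table.totals.get(denominator)
    if denom is None:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ValueError(f"denominator {denominator!r} is zero")
    df = table.to_frame()
    df["rpm"] = df["count"] / denom * 1e6
    df.attrs["denominator"] = denominator
    df.attrs["denominator_value"] = denom
    return df


def _write_tsv(df: pd.DataFrame, path: Path, header_meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _process_smallrna_sample(
    sample: SmallRnaSample, bundle: AnnotationBundle, config: RunConfig
):
    reads = read_fastq(sample.fastq)
    n_raw = len(reads)
    if config.adapter:
        trimmed = [trim_adapter(r, config.adapter) for r in reads]
        reads = [r for r in trimmed if r is not None]
    reads = size_select(reads, config.min_len, config.max_len)
    logger.info(
        "sample=%s stage=preprocess raw=%d kept=%d", sample.sample_id, n_raw, len(reads)
    )
    assignments = sequential_classify(
        reads, bundle, order=config.class_order, max_mismatch=config.max_mismatch
    )
    table = tabulate(assignments, sample_id=sample.sample_id)
    logger.info(
        "sample=%s stage=classify assigned=%.1f unassigned=%.1f",
        sample.sample_id,
        table.totals["total_genome"],
        table.class_total("unassigned"),
    )
    return reads, assignments, table


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written).

    Fails fast on missing inputs before any computation; each stage logs one
    structured line with input/output counts so read conservation can be
    audited from the log.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = (
        config.bundle
        if isinstance(config.bundle, AnnotationBundle)
        else load_bundle(config.bundle)
    )
    models = bundle.trna_by_name()
    manifest: dict = {
        "tdrprof_version": __version__,
        "seed": config.seed,
        "denominator": config.denominator,
        "class_order": list(config.class_order),
        "max_mismatch": config.max_mismatch,
        "outputs": {},
        "samples": {},
    }
    outputs = manifest["outputs"]

    per_sample_pct = []
    per_sample_arm = []
    lf_rows = []
    longshort_rows = []
    coverage_rows = []
    g22_rows = []
    pct_by_condition: dict[str, dict[str, list[float]]] = {}
    arm_by_condition: dict[str, list[float]] = {}

    for sample in config.smallrna_samples:
        reads, assignments, table = _process_smallrna_sample(sample, bundle, config)
        reads_by_id = {r.read_id: r for r in reads}
        rpm = normalize_counts(table, config.denominator)
        _write_tsv(
            rpm,
            outdir / f"{sample.sample_id}.rpm.tsv",
            {"denominator": config.denominator, "sample": sample.sample_id},
        )
        pct = table.class_percentages()
        per_sample_pct.append(
            {"sample_id": sample.sample_id, "condition": sample.condition, **pct}
        )
        for cls, value in pct.items():
            pct_by_condition.setdefault(cls, {}).setdefault(
                sample.condition, []
            ).append(value)

        arms = arm_summary(assignments, models)
        per_sample_arm.append(
            {
                "sample_id": sample.sample_id,
                "condition": sample.condition,
                "five_prime_count": arms.five_prime_count,
                "three_prime_count": arms.three_prime_count,
                "five_prime_pct": arms.five_prime_pct,
            }
        )
        arm_by_condition.setdefault(sample.condition, []).append(arms.five_prime_pct)

        lf, _ = length_first_nt(assignments, reads_by_id, cls="tRNA")
        lf_long = lf.reset_index().melt(
            id_vars="length", var_name="first_nt", value_name="count"
        )
        lf_long.insert(0, "sample_id", sample.sample_id)
        lf_rows.append(lf_long)

        profiles = build_profiles(assignments, reads_by_id, models)
        for name, prof in profiles.items():
            longshort_rows.append(
                {
                    "sample_id": sample.sample_id,
                    "trna": name,
                    "long_count": prof.long_count,
                    "short_count": prof.short_count,
                }
            )
            for pos, depth in enumerate(prof.depth):
                coverage_rows.append(
                    {
                        "sample_id": sample.sample_id,
                        "trna": name,
                        "pos": pos,
                        "depth": depth,
                    }
                )
        for gene_id in config.g22_genes:
            count, _hits = extract_22g(assignments, reads_by_id, gene_id, bundle)
            g22_rows.append(
                {
                    "sample_id": sample.sample_id,
                    "condition": sample.condition,
                    "gene_id": gene_id,
                    "count_22g": count,
                    "rpm_22g": count / table.totals["total_genome"] * 1e6,
                }
            )
        manifest["samples"][sample.sample_id] = {
            "condition": sample.condition,
            "n_reads": len(reads),
            "total_genome": table.totals["total_genome"],
            "genome_minus_rRNA": table.totals["genome_minus_rRNA"],
        }

    if config.smallrna_samples:
        panels = {
            "class_percentages.tsv": pd.DataFrame(per_sample_pct),
            "arm_fractions.tsv": pd.DataFrame(per_sample_arm),
            "length_first_nt.tsv": pd.concat(lf_rows, ignore_index=True),
            "long_short.tsv": pd.DataFrame(longshort_rows),
            "coverage.tsv": pd.DataFrame(coverage_rows),
        }
        if g22_rows:
            panels["g22_report.tsv"] = pd.DataFrame(g22_rows)
        for fname, df in panels.items():
            _write_tsv(df, outdir / fname, {"denominator": config.denominator})
            outputs[fname] = _checksum(outdir / fname)

        # between-condition statistics (one BH family per panel)
        conditions = sorted({s.condition for s in config.smallrna_samples})
        stat_rows = []
        if len(conditions) == 2:
            c0, c1 = conditions
            for cls, by_cond in sorted(pct_by_condition.items()):
                x, y = by_cond.get(c0, []), by_cond.get(c1, [])
                if x and y:
                    res = mann_whitney_two_sided(x, y)
                    stat_rows.append(
                        {
                            "family": "class_percentages",
                            "test": f"{cls}: {c0} vs {c1}",
                            "method": res.method,
                            "statistic": res.statistic,
                            "p": res.p_value,
                        }
                    )
            arm_x = [v for v in arm_by_condition.get(c0, []) if v == v]
            arm_y = [v for v in arm_by_condition.get(c1, []) if v == v]
            if len(arm_x) >= 2 and len(arm_y) >= 2:
                res = welch_t(arm_x, arm_y)
                stat_rows.append(
                    {
                        "family": "arm_fraction",
                        "test": f"five_prime_pct: {c0} vs {c1}",
                        "method": res.method,
                        "statistic": res.statistic,
                        "p": res.p_value,
                    }
                )
        if stat_rows:
            stats_df = pd.DataFrame(stat_rows)
            stats_df["p_adjusted"] = float("nan")
            for family, idx in stats_df.groupby("family").groups.items():
                stats_df.loc[idx, "p_adjusted"] = bh_adjust(
                    stats_df.loc[idx, "p"].to_numpy()
                )
            _write_tsv(stats_df, outdir / "class_stats.tsv")
            outputs["class_stats.tsv"] = _checksum(outdir / "class_stats.tsv")

    # embryo expression arm
    if config.expression_counts:
        counts = pd.read_csv(config.expression_counts, sep="\t", index_col=0)
        lengths = pd.read_csv(
            config.gene_lengths, sep="\t", index_col=0
        ).iloc[:, 0]
        mat = ExpressionMatrix(
            values=counts, condition=dict(config.expression_conditions), unit="counts"
        )
        tpm = tpm_normalize(mat, lengths)
        expressed = filter_expressed(tpm)
        cond_a, cond_b = config.de_conditions or tuple(
            sorted(set(config.expression_conditions.values()))
        )[:2]
        de = de_test(expressed, cond_a, cond_b)
        _write_tsv(
            de.reset_index(),
            outdir / "de_results.tsv",
            {"conditions": f"{cond_a} vs {cond_b}"},
        )
        outputs["de_results.tsv"] = _checksum(outdir / "de_results.tsv")
        groups = resolve_groups(
            de.index, prefix_rules=config.group_prefixes, explicit_lists=config.group_lists
        )
        if groups:
            report = group_cdf_analysis(de, groups)
            _write_tsv(report, outdir / "group_report.tsv")
            outputs["group_report.tsv"] = _checksum(outdir / "group_report.tsv")
        manifest["de"] = {
            "conditions": [cond_a, cond_b],
            "n_genes_tested": int(len(de)),
            "n_up": int((de["call"] == "up").sum()),
            "n_down": int((de["call"] == "down").sum()),
        }

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
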