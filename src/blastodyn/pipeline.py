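"""End-to-end orchestration: counts -> DE calls -> consensus -> GO dynamics,
plus the transcript-recovery stage and the qPCR 2^-ddCt helper.

Every run writes fixed-header TSV tables and a JSON run log recording all
thresholds actually applied, so a result can be reproduced from its log.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io as bio_io
from .consensus import ConsensusCall, consensus_table
from .go_dynamics import (
    CategoryDynamics,
    category_dynamics,
    consecutive_pairs,
    tally_categories,
)
from .pairwise_de import CountExperiment, test_comparison
from .transcript_recovery import (
    assign_taxonomy,
    classify_completeness,
    summarize_taxonomy,
)

logger = logging.getLogger("blastodyn.pipeline")

DEFAULT_COMPARISONS = (("preTO", "MC"), ("TO", "preTO"), ("MC", "TO"))


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """All inputs and thresholds of one run.

    Defaults are the study's printed values: per-test alpha 0.05 with both
    tests required, consensus over at least 3 of 5 replicates, GRV/GNV
    threshold 0.9, ORF length proxy 100 codons, best-hit e-value 1e-5.
    """

    counts: str = ""
    samples: str = ""
    go_map: str = ""
    transcripts: str = ""  # optional FASTA
    hits: str = ""  # optional 13-column hit table
    output_dir: str = "results"
    alpha: float = 0.05
    mode: str = "both"
    min_clues: int = 3
    tau: float = 0.9
    selection_rule: str = "or"
    min_aa: int = 100
    both_strands: bool = False
    evalue_max: float = 1e-5
    min_count: int = 0  # genes with max count below this are dropped
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    pairs: tuple[tuple[tuple[str, str], tuple[str, str]], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_clues < 1:
            raise ValueError("min_clues must be >= 1")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must be in (0, 1]")
        if self.min_aa < 1:
            raise ValueError("min_aa must be >= 1")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "comparisons" in raw:
            raw["comparisons"] = tuple(tuple(c) for c in raw["comparisons"])
        if "pairs" in raw:
            raw["pairs"] = tuple(
                (tuple(p[0]), tuple(p[1])) for p in raw["pairs"]
            )
        return cls(**raw)

    def effective_pairs(self):
        return tuple(self.pairs) or tuple(consecutive_pairs(list(self.comparisons)))


def _label(comparison: tuple[str, str]) -> str:
    return f"{comparison[0]}_vs_{comparison[1]}"


def consensus_frame(calls: Sequence[ConsensusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "comparison": [_label(c.comparison) for c in calls],
            "status": [c.status for c in calls],
            "support_up": [c.support_up for c in calls],
            "support_down": [c.support_down for c in calls],
            "n_replicates": [c.n_replicates for c in calls],
            "min_clues": [c.min_clues for c in calls],
        }
    )


def dynamics_frame(dynamics: Sequence[CategoryDynamics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "go_code": [d.go_code for d in dynamics],
            "go_name": [d.go_name for d in dynamics],
            "go_domain": [d.go_domain for d in dynamics],
            "first": [_label(d.pair[0]) for d in dynamics],
            "second": [_label(d.pair[1]) for d in dynamics],
            "D1": [d.d1 for d in dynamics],
            "U1": [d.u1 for d in dynamics],
            "D2": [d.d2 for d in dynamics],
            "U2": [d.u2 for d in dynamics],
            "GRV": [d.grv for d in dynamics],
            "GNV": [d.gnv for d in dynamics],
            "selected": [d.selected for d in dynamics],
        }
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage the config provides inputs for; returns the manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    try:
        experiment = bio_io.read_counts(config.counts, config.samples)
        go_map = bio_io.read_go_map(config.go_map)
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        raise StageError("input", str(exc)) from exc

    if config.min_count > 0:
        keep = experiment.counts.max(axis=1) >= config.min_count
        experiment = CountExperiment(
            counts=experiment.counts.loc[keep], samples=experiment.samples
        )
        logger.info("input: %d genes pass min_count=%d", keep.sum(), config.min_count)

    try:
        pair_calls = []
        for comparison in config.comparisons:
            pair_calls.extend(
                test_comparison(
                    experiment, comparison[0], comparison[1],
                    alpha=config.alpha, mode=config.mode,
                )
            )
        logger.info("pairwise_de: %d pair calls", len(pair_calls))
    except Exception as exc:
        raise StageError("pairwise_de", str(exc)) from exc

    try:
        consensus = consensus_table(pair_calls, min_clues=config.min_clues)
    except Exception as exc:
        raise StageError("consensus", str(exc)) from exc

    try:
        tallies = tally_categories(consensus, go_map)
        dynamics = category_dynamics(
            tallies, config.effective_pairs(), tau=config.tau,
            rule=config.selection_rule,
        )
    except Exception as exc:
        raise StageError("go_dynamics", str(exc)) from exc

    cons_df = consensus_frame(consensus)
    manifest["consensus"] = out_dir / "consensus.tsv"
    cons_df.to_csv(manifest["consensus"], sep="\t", index=False)

    tally_df = pd.DataFrame(
        {
            "go_code": [t.go_code for t in tallies],
            "go_name": [t.go_name for t in tallies],
            "go_domain": [t.go_domain for t in tallies],
            "comparison": [_label(t.comparison) for t in tallies],
            "down": [t.d for t in tallies],
            "up": [t.u for t in tallies],
        }
    )
    manifest["tallies"] = out_dir / "category_tallies.tsv"
    tally_df.to_csv(manifest["tallies"], sep="\t", index=False)

    manifest["dynamics"] = out_dir / "category_dynamics.tsv"
    dynamics_frame(dynamics).to_csv(manifest["dynamics"], sep="\t", index=False)

    if config.transcripts:
        try:
            records = bio_io.read_transcripts(config.transcripts)
            orf_calls = [
                classify_completeness(
                    r, min_aa=config.min_aa, both_strands=config.both_strands
                )
                for r in records
            ]
            orf_df = pd.DataFrame(
                {
                    "transcript_id": [c.transcript_id for c in orf_calls],
                    "frame": [c.frame for c in orf_calls],
                    "strand": [c.strand for c in orf_calls],
                    "start": [c.start for c in orf_calls],
                    "end": [c.end for c in orf_calls],
                    "aa_length": [c.aa_length for c in orf_calls],
                    "completeness": [c.completeness for c in orf_calls],
                }
            )
            manifest["orf_calls"] = out_dir / "orf_calls.tsv"
            orf_df.to_csv(manifest["orf_calls"], sep="\t", index=False)
        except Exception as exc:
            raise StageError("transcript_recovery", str(exc)) from exc

    if config.hits:
        try:
            hits = bio_io.read_hit_table(config.hits)
            assignments = assign_taxonomy(hits, evalue_max=config.evalue_max)
            summary = summarize_taxonomy(assignments)
            manifest["taxonomy"] = out_dir / "taxonomy_summary.tsv"
            summary.to_frame().to_csv(manifest["taxonomy"], sep="\t", index=False)
        except Exception as exc:
            raise StageError("transcript_recovery", str(exc)) from exc

    run_log = {
        "parameters": {
            "alpha": config.alpha,
            "mode": config.mode,
            "min_clues": config.min_clues,
            "tau": config.tau,
            "selection_rule": config.selection_rule,
            "min_aa": config.min_aa,
            "both_strands": config.both_strands,
            "evalue_max": config.evalue_max,
            "min_count": config.min_count,
            "comparisons": [list(c) for c in config.comparisons],
            "pairs": [[list(p[0]), list(p[1])] for p in config.effective_pairs()],
            "seed": config.seed,
        },
        "inputs": {
            "counts": config.counts,
            "samples": config.samples,
            "go_map": config.go_map,
            "transcripts": config.transcripts,
            "hits": config.hits,
        },
        "outputs": {k: str(v) for k, v in manifest.items()},
    }
    manifest["run_log"] = out_dir / "run_log.json"
    with open(manifest["run_log"], "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return manifest


# --- qPCR validation helper -------------------------------------------------

@dataclass(frozen=True)
class DdctMeasurement:
    """Cycle thresholds for one relative-quantification contrast."""

    ct_target_condition: float
    ct_reference_condition: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for v in (
            self.ct_target_condition, self.ct_reference_condition,
            self.ct_target_control, self.ct_reference_control,
        ):
            if not math.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and positive")


def ddct_fold_change(m: DdctMeasurement) -> float:
    """Relative fold change 2^-ddCt of target vs reference, condition vs control."""
    ddct = (m.ct_target_condition - m.ct_reference_condition) - (
        m.ct_target_control - m.ct_reference_control
    )
    return 2.0 ** (-ddct)


def ddct_compare(folds_a: Sequence[float], folds_b: Sequence[float]):
    """Two-sample t-test on log2 fold changes of replicated measurements."""
    return stats.ttest_ind(np.log2(folds_a), np.log2(folds_b))


def render_overview(dynamics: Sequence[CategoryDynamics], top_n: int) -> pd.DataFrame:
    """Per comparison pair and GO domain, the ``top_n`` categories by total
    DE-gene count, with down/up percentages per comparison and the metrics."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not dynamics:
        raise ValueError("empty dynamics")
    rows = []
    for d in dynamics:
        n1 = d.d1 + d.u1
        n2 = d.d2 + d.u2
        rows.append(
            {
                "go_domain": d.go_domain,
                "pair": f"{_label(d.pair[0])} -> {_label(d.pair[1])}",
                "go_code": d.go_code,
                "go_name": d.go_name,
                "D1": d.d1, "U1": d.u1, "D2": d.d2, "U2": d.u2,
                "total": d.total,
                "down_pct_1": 100.0 * d.d1 / n1 if n1 else math.nan,
                "up_pct_1": 100.0 * d.u1 / n1 if n1 else math.nan,
                "down_pct_2": 100.0 * d.d2 / n2 if n2 else math.nan,
                "up_pct_2": 100.0 * d.u2 / n2 if n2 else math.nan,
                "GRV": d.grv, "GNV": d.gnv, "selected": d.selected,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["pair", "go_domain", "total", "go_code"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return df.groupby(["pair", "go_domain"], sort=False).head(top_n).reset_index(drop=True)
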