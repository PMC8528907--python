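"""End-to-end disturbed-vs-control diversity comparison.

`DiversityComparison` is the model object: it is built from one or two
count tables (taxonomic OTU counts and/or functional GO-term counts) plus
sample metadata, and `fit()` runs the analysis — joint coverage-based
rarefaction of all taxonomic samples to the lowest attainable coverage with
inverse-Simpson (2D) diversity, Chao-Shen effective-function (1D) diversity
per functional sample, and a Welch/Anderson-Darling group comparison per
index.  `DiversityComparisonResults` carries per-sample diagnostics, the
summary rows, and writers for TSV/JSON reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diversity import (
    DiversityResult,
    chao_shen_effective_functions,
    rarefy_to_common_coverage,
)
from .stats import GroupSummary, WelchResult, compare_groups, DEFAULT_ALPHA
from .tables import CountTable, SampleMetadata, split_groups

__all__ = [
    "AnalysisRow",
    "DiversityComparison",
    "DiversityComparisonResults",
    "run_taxonomic_analysis",
    "run_functional_analysis",
    "write_report",
]

INDEX_TAXONOMIC = "taxonomic_2D"
INDEX_FUNCTIONAL = "functional_1D"


@dataclass(frozen=True)
class AnalysisRow:
    """One summary-table row: an index name, both group summaries, Welch."""

    index: str  # "taxonomic_2D" | "functional_1D"
    disturbed: GroupSummary
    control: GroupSummary
    welch: WelchResult
    per_sample: tuple[DiversityResult, ...] = ()
    target_coverage: float | None = None


def _group_values(
    results: Sequence[DiversityResult],
    disturbed_ids: set[str],
    control_ids: set[str],
) -> tuple[list[float], list[float]]:
    dist = [r.value for r in results if r.sample_id in disturbed_ids]
    ctrl = [r.value for r in results if r.sample_id in control_ids]
    return dist, ctrl


def run_taxonomic_analysis(
    table: CountTable,
    metadata: Sequence[SampleMetadata],
    alpha: float = DEFAULT_ALPHA,
    mode: Literal["analytic", "montecarlo"] = "analytic",
    reps: int = 1000,
    seed: int | None = None,
) -> AnalysisRow:
    """Taxonomic 2D row: joint rarefaction to common coverage, then Welch.

    The rarefaction target is computed over the union of both groups — a
    single global coverage, matching the convention of rarefying to the
    dataset with the lowest coverage.
    """
    disturbed, control = split_groups(table, metadata, "taxonomic")
    if len(disturbed) < 2 or len(control) < 2:
        raise ValueError("taxonomic analysis requires >= 2 samples per group")
    all_samples = disturbed + control
    results = rarefy_to_common_coverage(all_samples, mode=mode, reps=reps, seed=seed)
    d_ids = {v.sample_id for v in disturbed}
    c_ids = {v.sample_id for v in control}
    d_vals, c_vals = _group_values(results, d_ids, c_ids)
    s_d, s_c, welch = compare_groups(d_vals, c_vals, alpha=alpha)
    return AnalysisRow(
        INDEX_TAXONOMIC, s_d, s_c, welch,
        per_sample=tuple(results),
        target_coverage=results[0].coverage,
    )


def run_functional_analysis(
    table: CountTable,
    metadata: Sequence[SampleMetadata],
    alpha: float = DEFAULT_ALPHA,
) -> AnalysisRow:
    """Functional 1D row: Chao-Shen effective functions per sample, then Welch."""
    disturbed, control = split_groups(table, metadata, "functional")
    if len(disturbed) < 2 or len(control) < 2:
        raise ValueError("functional analysis requires >= 2 samples per group")
    results = [chao_shen_effective_functions(v) for v in disturbed + control]
    d_ids = {v.sample_id for v in disturbed}
    c_ids = {v.sample_id for v in control}
    d_vals, c_vals = _group_values(results, d_ids, c_ids)
    s_d, s_c, welch = compare_groups(d_vals, c_vals, alpha=alpha)
    return AnalysisRow(INDEX_FUNCTIONAL, s_d, s_c, welch, per_sample=tuple(results))


class DiversityComparison:
    """Disturbed-vs-control diversity model over count tables.

    Parameters
    ----------
    taxonomic, functional : CountTable or None
        OTU and/or GO-term count tables; at least one must be given.
    metadata : sequence of SampleMetadata
        Group and assay assignment covering every sample in each table.
    alpha : float
        Significance threshold for the Welch tests.
    """

    def __init__(
        self,
        taxonomic: CountTable | None = None,
        functional: CountTable | None = None,
        metadata: Sequence[SampleMetadata] = (),
        alpha: float = DEFAULT_ALPHA,
    ) -> None:
        if taxonomic is None and functional is None:
            raise ValueError("at least one of taxonomic/functional tables is required")
        self.taxonomic = taxonomic
        self.functional = functional
        self.metadata = list(metadata)
        self.alpha = alpha

    @classmethod
    def from_files(
        cls,
        taxonomic: str | Path | None = None,
        functional: str | Path | None = None,
        metadata: str | Path | None = None,
        alpha: float = DEFAULT_ALPHA,
    ) -> "DiversityComparison":
        from .tables import read_count_table, read_metadata

        if metadata is None:
            raise ValueError("a metadata table is required")
        return cls(
            taxonomic=read_count_table(taxonomic) if taxonomic else None,
            functional=read_count_table(functional) if functional else None,
            metadata=read_metadata(metadata),
            alpha=alpha,
        )

    def _provenance(self, mode: str, reps: int, seed: int | None) -> dict:
        h = hashlib.sha256()
        for tbl in (self.taxonomic, self.functional):
            if tbl is not None:
                h.update("\x00".join(tbl.feature_ids).encode())
                h.update("\x00".join(tbl.sample_ids).encode())
                h.update(np.ascontiguousarray(tbl.counts).tobytes())
        for m in self.metadata:
            h.update(f"{m.sample_id}|{m.group}|{m.assay}|{m.label}".encode())
        return {
            "tool": "divshift",
            "version": __version__,
            "input_hash": h.hexdigest(),
            "alpha": self.alpha,
            "rarefaction_mode": mode,
            "montecarlo_reps": reps if mode == "montecarlo" else None,
            "seed": seed,
        }

    def fit(
        self,
        mode: Literal["analytic", "montecarlo"] = "analytic",
        reps: int = 1000,
        seed: int | None = None,
    ) -> "DiversityComparisonResults":
        rows: list[AnalysisRow] = []
        if self.taxonomic is not None:
            rows.append(
                run_taxonomic_analysis(
                    self.taxonomic, self.metadata, alpha=self.alpha,
                    mode=mode, reps=reps, seed=seed,
                )
            )
        if self.functional is not None:
            rows.append(
                run_functional_analysis(self.functional, self.metadata, alpha=self.alpha)
            )
        return DiversityComparisonResults(
            self, tuple(rows), self._provenance(mode, reps, seed)
        )


class DiversityComparisonResults:
    """Fitted disturbed-vs-control comparison: summary rows + diagnostics."""

    def __init__(
        self,
        model: DiversityComparison,
        rows: tuple[AnalysisRow, ...],
        provenance: dict,
    ) -> None:
        if not rows:
            raise ValueError("results require at least one analysis row")
        self.model = model
        self.rows = rows
        self.provenance = provenance

    def row(self, index: str) -> AnalysisRow:
        for r in self.rows:
            if r.index == index:
                return r
        raise KeyError(f"no analysis row named {index!r}")

    def summary_frame(self) -> pd.DataFrame:
        """The summary table as a DataFrame (one row per diversity index)."""
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "index": r.index,
                    "disturbed_mean": r.disturbed.mean,
                    "disturbed_sd": r.disturbed.sd,
                    "disturbed_n": r.disturbed.n,
                    "disturbed_ad_p": r.disturbed.ad_p,
                    "control_mean": r.control.mean,
                    "control_sd": r.control.sd,
                    "control_n": r.control.n,
                    "control_ad_p": r.control.ad_p,
                    "welch_t": r.welch.t,
                    "welch_df": r.welch.df,
                    "welch_p": r.welch.p,
                    "significant": r.welch.significant,
                }
            )
        return pd.DataFrame(recs)

    def per_sample_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            for d in r.per_sample:
                recs.append(
                    {
                        "index": r.index,
                        "sample_id": d.sample_id,
                        "estimator": d.estimator,
                        "q": d.q,
                        "m": d.rarefied_to,
                        "coverage": d.coverage,
                        "value": d.value,
                    }
                )
        return pd.DataFrame(recs)

    def summary(self) -> str:
        """Human-readable summary table (3 significant digits)."""
        lines = [
            "Disturbed-vs-control diversity comparison",
            f"  alpha = {self.model.alpha}, divshift {self.provenance['version']}",
            "",
            f"{'index':<15}{'group':<11}{'mean':>10}{'sd':>10}{'n':>4}"
            f"{'AD p':>10}{'Welch t':>10}{'df':>8}{'Welch p':>12}  sig",
        ]
        for r in self.rows:
            for which, s in (("disturbed", r.disturbed), ("control", r.control)):
                ad = "n/a" if s.ad_p is None else f"{s.ad_p:.3g}"
                stat = (
                    f"{r.welch.t:>10.3g}{r.welch.df:>8.3g}{r.welch.p:>12.3g}"
                    f"  {'*' if r.welch.significant else ''}"
                    if which == "disturbed"
                    else " " * 32
                )
                lines.append(
                    f"{r.index:<15}{which:<11}{s.mean:>10.3g}{s.sd:>10.3g}"
                    f"{s.n:>4}{ad:>10}{stat}"
                )
            if r.target_coverage is not None:
                lines.append(f"{'':<15}rarefied to common coverage "
                             f"C* = {r.target_coverage:.6f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out: dict = {"provenance": self.provenance, "rows": []}
        for r in self.rows:
            out["rows"].append(
                {
                    "index": r.index,
                    "target_coverage": r.target_coverage,
                    "disturbed": {
                        "mean": r.disturbed.mean, "sd": r.disturbed.sd,
                        "n": r.disturbed.n, "ad_p": r.disturbed.ad_p,
                        "ad_status": r.disturbed.ad_status,
                    },
                    "control": {
                        "mean": r.control.mean, "sd": r.control.sd,
                        "n": r.control.n, "ad_p": r.control.ad_p,
                        "ad_status": r.control.ad_status,
                    },
                    "welch": {
                        "t": r.welch.t, "df": r.welch.df,
                        "p": r.welch.p, "significant": r.welch.significant,
                    },
                    "per_sample": [
                        {
                            "sample_id": d.sample_id, "estimator": d.estimator,
                            "q": d.q, "m": d.rarefied_to,
                            "coverage": d.coverage, "value": d.value,
                        }
                        for d in r.per_sample
                    ],
                }
            )
        return out


def write_report(results: DiversityComparisonResults, path: str | Path) -> list[Path]:
    """Write TSV (3 sig. digits), full-precision JSON, and a decision log."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []

    tsv = path / "report.tsv"
    frame = results.summary_frame().copy()
    for col in frame.columns:
        if frame[col].dtype == np.float64:
            frame[col] = frame[col].map(lambda x: f"{x:.6g}" if pd.notna(x) else "NA")
    frame.to_csv(tsv, sep="\t", index=False)
    written.append(tsv)

    js = path / "report.json"
    with js.open("w", encoding="utf-8") as fh:
        json.dump(results.to_dict(), fh, indent=2)
        fh.write("\n")
    written.append(js)

    per_sample = path / "per_sample.tsv"
    results.per_sample_frame().to_csv(per_sample, sep="\t", index=False)
    written.append(per_sample)

    log = path / "analysis.log"
    with log.open("w", encoding="utf-8") as fh:
        for r in results.rows:
            if r.target_coverage is not None:
                fh.write(f"{r.index}: common target coverage C* = {r.target_coverage!r}\n")
                for d in r.per_sample:
                    fh.write(f"  {d.sample_id}: m = {d.rarefied_to}\n")
            else:
                fh.write(f"{r.index}: full-sample estimation (no rarefaction)\n")
    written.append(log)
    return written
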