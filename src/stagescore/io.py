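"""Readers, writers and the bundled validation fixture.

CSV (UTF-8, header, comma) is the lingua franca for tabular data and JSON
for nested reports.  The bundled ``table3`` fixture holds the 58 validation
sentences with their expert MAP scores and the protocol's STAGES scores,
transcribed verbatim (typography included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import AgreementResult, CrossTab
from .calibration import RegressionRow, SubsampleStat
from .errors import FixtureNotFoundError, FormatError, InvalidLevelError
from .pipeline import SentenceClassification, SentenceRecord
from .stages_model import GRID, is_on_grid

_FIXTURES = {"table3": "table3.csv"}


@dataclass
class Dataset:
    """A list of sentence records with a provenance note."""

    records: list[SentenceRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self, col_a: str = "map_score", col_b: str = "stages_score"
              ) -> list[tuple[float, float]]:
        """Extract (rater A, rater B) score pairs from records carrying both."""
        out = []
        for rec in self.records:
            a = getattr(rec, col_a)
            b = getattr(rec, col_b)
            if a is not None and b is not None:
                out.append((a, b))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "text": [r.text for r in self.records],
                "map_score": [r.map_score for r in self.records],
                "stages_score": [r.stages_score for r in self.records],
            }
        )


def _records_from_frame(df: pd.DataFrame, origin: str) -> list[SentenceRecord]:
    for required in ("id", "text"):
        if required not in df.columns:
            raise FormatError(f"{origin}: missing required column {required!r}")
    ids = df["id"].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise FormatError(f"{origin}: duplicate id {dup.iloc[0]!r}")
    records = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        text = str(row.text)
        if not text.strip():
            raise FormatError(f"{origin}: row {row_number}: empty sentence text")
        scores = {}
        for col in ("map_score", "stages_score"):
            value = getattr(row, col, None)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                scores[col] = None
                continue
            value = float(value)
            if not is_on_grid(value):
                raise InvalidLevelError(
                    f"{origin}: row {row_number}: {col}={value} is not on the "
                    f"STAGES grid {GRID[0]}..{GRID[-1]}"
                )
            scores[col] = value
        records.append(SentenceRecord(id=str(row.id), text=text, **scores))
    return records


def load_fixture(name: str = "table3") -> Dataset:
    """Load a bundled fixture by name.

    ``table3`` is the 58-sentence validation set: ids t-1..t-58, sentence
    text, expert MAP score, and the STAGES score produced by the protocol.
    """
    if name not in _FIXTURES:
        raise FixtureNotFoundError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    ref = resources.files("stagescore").joinpath("data", _FIXTURES[name])
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, encoding="utf-8")
    return Dataset(records=_records_from_frame(df, f"fixture {name}"),
                   provenance=f"bundled fixture {name!r}")


def read_sentences(path: str | Path) -> Dataset:
    """Read a sentences CSV (columns id, text, optional map_score /
    stages_score); scores are validated against the grid."""
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    return Dataset(records=_records_from_frame(df, str(path)), provenance=str(path))


def write_sentences(dataset: Dataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def scores_frame(classifications: Sequence[SentenceClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.sentence_id for c in classifications],
            "median_q1": [c.median_q1 for c in classifications],
            "median_q2": [c.median_q2 for c in classifications],
            "median_q3": [c.median_q3 for c in classifications],
            "median_level": [c.median_level for c in classifications],
            "n_runs": [c.n_runs for c in classifications],
        }
    )


def write_scores(classifications: Sequence[SentenceClassification],
                 path: str | Path) -> None:
    scores_frame(classifications).to_csv(path, index=False, encoding="utf-8")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    for col in ("id", "median_level"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


# ---------------------------------------------------------------------------
# Pairs
# ---------------------------------------------------------------------------


def read_pairs(path: str | Path, col_a: str = "score_a", col_b: str = "score_b"
               ) -> list[tuple[float, float]]:
    """Read a pairs CSV (columns id, score_a, score_b by default)."""
    df = pd.read_csv(path, encoding="utf-8")
    for col in (col_a, col_b):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    pairs = []
    for row_number, (a, b) in enumerate(zip(df[col_a], df[col_b]), start=2):
        a, b = float(a), float(b)
        for value in (a, b):
            if not is_on_grid(value):
                raise InvalidLevelError(
                    f"{path}: row {row_number}: {value} is not on the STAGES grid"
                )
        pairs.append((a, b))
    return pairs


def write_pairs(pairs: Sequence[tuple[float, float]], path: str | Path,
                ids: Sequence[str] | None = None) -> None:
    if ids is None:
        ids = [f"p-{i + 1}" for i in range(len(pairs))]
    pd.DataFrame(
        {"id": list(ids), "score_a": [a for a, _ in pairs], "score_b": [b for _, b in pairs]}
    ).to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Cross-tab, agreement, calibration reports
# ---------------------------------------------------------------------------


def crosstab_frame(tab: CrossTab) -> pd.DataFrame:
    """Cross-tab as a labeled DataFrame with Total row and column: 12
    labeled rows and columns on the full grid plus marginals."""
    labels = [f"{lvl:g}" for lvl in tab.grid]
    df = pd.DataFrame(tab.counts, index=labels, columns=labels)
    df["Total"] = df.sum(axis=1)
    df.loc["Total"] = df.sum(axis=0)
    return df


def write_crosstab(tab: CrossTab, path: str | Path) -> None:
    crosstab_frame(tab).to_csv(path, index_label="", encoding="utf-8")


def read_crosstab(path: str | Path) -> CrossTab:
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    body = df.drop(index="Total", columns="Total")
    counts = body.to_numpy(dtype=int)
    tab = CrossTab(counts=counts)
    # integrity: marginals must match the stored totals
    if not (df.loc["Total", "Total"] == counts.sum()):
        raise FormatError(f"{path}: totals do not match the table body")
    return tab


def write_agreement(result: AgreementResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {"kappa": result.kappa, "se": result.se, "ci_low": result.ci_low,
             "ci_high": result.ci_high, "n": result.n},
            fh, indent=2)
        fh.write("\n")


def read_agreement(path: str | Path) -> AgreementResult:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return AgreementResult(**data)


def write_regression(rows: Sequence[RegressionRow], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in rows]).to_csv(path, index=False, encoding="utf-8")


def read_regression(path: str | Path) -> list[RegressionRow]:
    df = pd.read_csv(path, encoding="utf-8")
    return [RegressionRow(int(r.window_start), str(r.quantity), float(r.slope),
                          float(r.intercept))
            for r in df.itertuples(index=False)]


def write_subsample(stats_: Sequence[SubsampleStat], path: str | Path) -> None:
    pd.DataFrame([s.__dict__ for s in stats_]).to_csv(path, index=False, encoding="utf-8")


def read_subsample(path: str | Path) -> list[SubsampleStat]:
    df = pd.read_csv(path, encoding="utf-8")
    return [SubsampleStat(int(r.sample_size), float(r.mean_abs_diff),
                          float(r.std_abs_diff), int(r.n_combos))
            for r in df.itertuples(index=False)]


def write_reports(out_dir: str | Path,
                  classifications: Sequence[SentenceClassification] | None = None,
                  crosstab: CrossTab | None = None,
                  agreement: AgreementResult | None = None,
                  regression: Sequence[RegressionRow] | None = None,
                  subsample: Sequence[SubsampleStat] | None = None) -> list[Path]:
    """Write whichever results are supplied into ``out_dir``; returns the
    paths written.  Every file round-trips through the matching reader."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if classifications is not None:
        p = out_dir / "scores.csv"
        write_scores(classifications, p)
        written.append(p)
    if crosstab is not None:
        p = out_dir / "crosstab.csv"
        write_crosstab(crosstab, p)
        written.append(p)
    if agreement is not None:
        p = out_dir / "agreement.json"
        write_agreement(agreement, p)
        written.append(p)
    if regression is not None:
        p = out_dir / "run_calibration.csv"
        write_regression(regression, p)
        written.append(p)
    if subsample is not None:
        p = out_dir / "item_calibration.csv"
        write_subsample(subsample, p)
        written.append(p)
    return written
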