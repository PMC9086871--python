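"""Precision evaluation: annotation sampling, agreement, adjudication.

The pipeline's output is audited by sampling matched units (tweets and
profiles), having two annotators independently label each as a true or
false positive, measuring chance-corrected agreement (Cohen's κ),
resolving disagreements by adjudication, and computing

    precision = TP / (TP + FP)

per channel and pooled.  κ is computed on the pre-adjudication labels —
that is what independent dual annotation measures — while precision is
computed on the post-adjudication finals.

Annotation I/O is plain CSV (columns: unit_id, channel, text, label_a,
label_b, adjudicated) so external annotators can work in spreadsheets.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .patterns import Channel

__all__ = [
    "AnnotationRecord",
    "EvalMetrics",
    "REFERENCE_VALUES",
    "sample_for_annotation",
    "cohen_kappa",
    "adjudicate",
    "compute_metrics",
    "read_annotations",
    "write_annotations",
]

TP, FP = "TP", "FP"

#: Values from the original 2020–2021 Twitter-stream deployment of this
#: kind of pipeline, displayed in reports for orientation only.  They
#: depend on the live stream and its annotator pool and cannot be
#: recomputed from a synthetic corpus.
REFERENCE_VALUES = {
    "n_users": 10043,
    "n_matched_tweets": 8603,
    "n_tweet_users": 6358,
    "n_profile_users": 4127,
    "kappa_overall": 0.81,
    "kappa_tweets": 0.83,
    "kappa_profiles": 0.79,
    "state_coverage_pct": 87.6,
    "county_coverage_pct": 71.2,
    "age_coverage_pct": 47.6,
    "mean_age": 31.9,
    "sd_age": 13.1,
    "median_age": 29,
}


@dataclass
class AnnotationRecord:
    unit_id: str
    channel: Channel
    label_a: str
    label_b: str
    final: str | None = None
    text: str = ""

    def __post_init__(self) -> None:
        for lbl in (self.label_a, self.label_b):
            if lbl not in (TP, FP):
                raise ValueError(f"label must be TP or FP, got {lbl!r}")
        if self.label_a == self.label_b and self.final is None:
            self.final = self.label_a


@dataclass
class ChannelMetrics:
    n: int
    tp: int
    fp: int
    precision: float
    kappa: float


@dataclass
class EvalMetrics:
    tweets: ChannelMetrics | None
    profiles: ChannelMetrics | None
    n_total: int
    precision_overall: float
    kappa_overall: float


def sample_for_annotation(
    units: Sequence[tuple[str, Channel]],
    n_tweets: int,
    n_profiles: int,
    seed: int,
) -> list[tuple[str, Channel]]:
    """Uniform without-replacement sample, per channel, reproducible.

    ``units`` are (unit_id, channel) pairs.  Raises when a channel has
    fewer units than requested.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[str, Channel]] = []
    for channel, n in ((Channel.TWEET, n_tweets), (Channel.PROFILE, n_profiles)):
        pool = sorted(u for u in units if u[1] == channel)
        if len(pool) < n:
            raise ValueError(
                f"cannot sample {n} {channel.value} units from {len(pool)}"
            )
        idx = rng.choice(len(pool), size=n, replace=False)
        out.extend(pool[i] for i in sorted(idx))
    return out


def cohen_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Cohen's κ = (p_o − p_e) / (1 − p_e) for two annotators.

    p_e comes from each annotator's marginal label frequencies.  In the
    degenerate case p_e = 1 (both annotators constant and identical) κ
    is defined as 1.0, with a warning.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    n = len(labels_a)
    if n < 2:
        raise ValueError("need at least 2 labelled units")
    labels = sorted(set(labels_a) | set(labels_b))
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    p_e = sum(
        (list(labels_a).count(c) / n) * (list(labels_b).count(c) / n)
        for c in labels
    )
    if p_e == 1.0:
        warnings.warn("both annotators constant and identical; kappa defined as 1.0")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def adjudicate(
    records: Iterable[AnnotationRecord],
    adjudications: dict[str, str] | None = None,
) -> list[AnnotationRecord]:
    """Fill final labels: agreed label, else the adjudicated label.

    Raises with the offending unit_ids when a disagreement has no
    adjudication.
    """
    adjudications = adjudications or {}
    missing: list[str] = []
    out: list[AnnotationRecord] = []
    for rec in records:
        if rec.label_a == rec.label_b:
            rec.final = rec.label_a
        elif rec.final is None:
            adj = adjudications.get(rec.unit_id)
            if adj is None:
                missing.append(rec.unit_id)
            else:
                rec.final = adj
        out.append(rec)
    if missing:
        raise ValueError(f"unresolved disagreements for units: {missing}")
    return out


def _channel_metrics(records: list[AnnotationRecord]) -> ChannelMetrics | None:
    if not records:
        return None
    tp = sum(1 for r in records if r.final == TP)
    fp = sum(1 for r in records if r.final == FP)
    return ChannelMetrics(
        n=len(records),
        tp=tp,
        fp=fp,
        precision=tp / (tp + fp),
        kappa=cohen_kappa([r.label_a for r in records], [r.label_b for r in records]),
    )


def compute_metrics(records: Iterable[AnnotationRecord]) -> EvalMetrics:
    """Per-channel and pooled precision and κ.

    All records must carry final labels (run :func:`adjudicate` first).
    A channel with zero records has absent metrics, not zero.
    """
    records = list(records)
    if not records:
        raise ValueError("no annotation records")
    unresolved = [r.unit_id for r in records if r.final is None]
    if unresolved:
        raise ValueError(f"records without final labels: {unresolved}")

    tweets = [r for r in records if r.channel == Channel.TWEET]
    profiles = [r for r in records if r.channel == Channel.PROFILE]
    tp = sum(1 for r in records if r.final == TP)
    fp = len(records) - tp
    return EvalMetrics(
        tweets=_channel_metrics(tweets),
        profiles=_channel_metrics(profiles),
        n_total=len(records),
        precision_overall=tp / (tp + fp),
        kappa_overall=cohen_kappa(
            [r.label_a for r in records], [r.label_b for r in records]
        ),
    )


_CSV_COLUMNS = ["unit_id", "channel", "text", "label_a", "label_b", "adjudicated"]


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for r in records:
            w.writerow(
                [r.unit_id, r.channel.value, r.text, r.label_a, r.label_b, r.final or ""]
            )


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    out: list[AnnotationRecord] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                AnnotationRecord(
                    unit_id=row["unit_id"],
                    channel=Channel(row["channel"]),
                    label_a=row["label_a"],
                    label_b=row["label_b"],
                    final=row.get("adjudicated") or None,
                    text=row.get("text", ""),
                )
            )
    return out
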