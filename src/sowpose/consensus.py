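"""Expert-vote aggregation: majority scoring, the difference-between-answers
(DBA) statistic, confidence bands, outlier-expert removal, repository
filtering, and lateral-to-dorsal score transfer.

The DBA of a vote vector ``v`` is ``max(v) - (sum(v) - max(v))``, i.e.
``2*max(v) - sum(v)``, evaluated literally with no clamping.  Two readings
of the vote vector are supported: the raw votes (default) or the set of
distinct answered scores (``mode='distinct'``).  The band table maps
DBA < -1 to 0% confidence, [-1, 0) to 25%, [0, 1) to 75% and [1, 2) to
100%; values >= 2 fall outside the printed bands and are, by default,
reported as ``out_of_range`` and excluded from repositories (policy
``clamp`` maps them to 100% instead).

Note the bands interact oddly with the raw reading: a large unanimous
panel drives ``2*max - sum`` far negative, so unanimity lands in the
low-confidence bands.  This is a property of the published procedure and
is surfaced rather than corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "UNRESOLVED",
    "BANDS",
    "VoteTable",
    "ConsensusResult",
    "Repository",
    "majority_score",
    "compute_dba",
    "confidence_from_dba",
    "score_videos",
    "detect_outlier_experts",
    "build_repository",
    "transfer_scores",
]

logger = logging.getLogger(__name__)

#: Sentinel for "no score obtained a strict majority".
UNRESOLVED = None

#: Confidence bands in increasing-DBA order, plus the out-of-band label.
BANDS = ("0%", "25%", "75%", "100%")
OUT_OF_RANGE = "out_of_range"
_ACCEPTED_BANDS = frozenset({"75%", "100%"})

_VOTE_COLUMNS = ("video_id", "expert_id", "score")


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus outcome for one video."""

    video_id: str
    final_score: Optional[int]
    dba: float
    band: str

    @property
    def resolved(self) -> bool:
        return self.final_score is not None

    @property
    def accepted(self) -> bool:
        """True when the video qualifies for the repository."""
        return self.resolved and self.band in _ACCEPTED_BANDS


class VoteTable:
    """Expert x video table of ordinal locomotion scores (0-3).

    Backed by a long-format DataFrame with columns ``video_id``,
    ``expert_id``, ``score``; at most one vote per (video, expert).
    """

    def __init__(self, df: pd.DataFrame):
        missing = set(_VOTE_COLUMNS) - set(df.columns)
        if missing:
            raise ParseError(f"vote table missing columns {sorted(missing)}")
        extra = set(df.columns) - set(_VOTE_COLUMNS)
        if extra:
            raise ParseError(f"vote table has unknown columns {sorted(extra)}")
        df = df.copy()
        scores = pd.to_numeric(df["score"], errors="coerce")
        if scores.isna().any():
            row = int(df.index[scores.isna()][0])
            raise ParseError(f"non-numeric score at row {row}")
        if not np.array_equal(scores, scores.astype(int)):
            raise ValidationError("scores must be integral")
        df["score"] = scores.astype(int)
        if ((df["score"] < 0) | (df["score"] > 3)).any():
            raise ValidationError("scores must be in 0..3")
        df["video_id"] = df["video_id"].astype(str)
        df["expert_id"] = df["expert_id"].astype(str)
        dup = df.duplicated(subset=["video_id", "expert_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["video_id", "expert_id"]].tolist()
            raise ValidationError(f"duplicate vote for (video, expert) = {tuple(pair)}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "VoteTable":
        return cls(pd.DataFrame(list(records), columns=list(_VOTE_COLUMNS)))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "VoteTable":
        try:
            df = pd.read_csv(path, dtype={"video_id": str, "expert_id": str})
        except FileNotFoundError:
            raise
        except Exception as exc:  # malformed CSV
            raise ParseError(f"cannot parse vote CSV {path}: {exc}") from exc
        return cls(df)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.df.to_csv(path, index=False)

    @property
    def videos(self) -> list[str]:
        return list(dict.fromkeys(self.df["video_id"]))

    @property
    def experts(self) -> list[str]:
        return list(dict.fromkeys(self.df["expert_id"]))

    def votes_for(self, video_id: str) -> np.ndarray:
        sel = self.df.loc[self.df["video_id"] == video_id, "score"]
        return sel.to_numpy(dtype=int)

    def drop_experts(self, expert_ids: Iterable[str]) -> "VoteTable":
        drop = set(expert_ids)
        return VoteTable(self.df[~self.df["expert_id"].isin(drop)])

    def __len__(self) -> int:
        return len(self.df)


def majority_score(votes: Sequence[int]) -> Optional[int]:
    """Score held by strictly more than half the votes, else ``UNRESOLVED``."""
    votes = np.asarray(votes, dtype=int)
    if votes.size == 0:
        raise ValidationError("empty vote list")
    values, counts = np.unique(votes, return_counts=True)
    top = counts.argmax()
    if counts[top] * 2 > votes.size:
        return int(values[top])
    return UNRESOLVED


def compute_dba(votes: Sequence[int], mode: str = "raw") -> float:
    """Difference between answers: ``max(v) - (sum(v) - max(v))``.

    ``mode='raw'`` uses the vote vector as given; ``mode='distinct'`` uses
    the set of distinct answered scores.
    """
    votes = np.asarray(votes, dtype=float)
    if votes.size == 0:
        raise ValidationError("empty vote list")
    if mode == "distinct":
        votes = np.unique(votes)
    elif mode != "raw":
        raise ValidationError(f"unknown DBA mode {mode!r}")
    return float(2.0 * votes.max() - votes.sum())


def confidence_from_dba(dba: float, policy: str = "out_of_range") -> str:
    """Map a DBA value onto the confidence bands.

    Bands: dba < -1 -> 0%; [-1, 0) -> 25%; [0, 1) -> 75%; [1, 2) -> 100%.
    ``dba >= 2`` is beyond the printed table; policy ``out_of_range``
    (default) labels it as such, ``clamp`` maps it to 100%.
    """
    if policy not in ("out_of_range", "clamp"):
        raise ValidationError(f"unknown band policy {policy!r}")
    if dba < -1:
        return "0%"
    if dba < 0:
        return "25%"
    if dba < 1:
        return "75%"
    if dba < 2:
        return "100%"
    return "100%" if policy == "clamp" else OUT_OF_RANGE


def score_videos(
    table: VoteTable,
    dba_mode: str = "raw",
    band_policy: str = "out_of_range",
) -> list[ConsensusResult]:
    """Majority score, DBA and confidence band for every voted video."""
    results = []
    for vid in table.videos:
        votes = table.votes_for(vid)
        dba = compute_dba(votes, mode=dba_mode)
        results.append(
            ConsensusResult(
                video_id=vid,
                final_score=majority_score(votes),
                dba=dba,
                band=confidence_from_dba(dba, policy=band_policy),
            )
        )
    return results


def detect_outlier_experts(table: VoteTable, fence: float = 1.5) -> list[str]:
    """Flag experts whose votes deviate anomalously from the panel.

    Per expert the deviation is the mean absolute difference between their
    vote and the panel median for that video; experts beyond the Tukey
    fence ``Q3 + fence * IQR`` of the deviation distribution are flagged.
    """
    experts = table.experts
    if len(experts) < 4:
        raise ValidationError("need at least 4 experts for fence-based detection")
    medians = table.df.groupby("video_id")["score"].median()
    dev = (table.df["score"] - table.df["video_id"].map(medians)).abs()
    per_expert = dev.groupby(table.df["expert_id"]).mean()
    q1, q3 = np.percentile(per_expert.to_numpy(), [25, 75])
    threshold = q3 + fence * (q3 - q1)
    flagged = sorted(per_expert.index[per_expert > threshold])
    if flagged:
        logger.info("flagged outlier experts: %s (fence=%.3g)", flagged, fence)
    return flagged


@dataclass
class Repository:
    """Filtered video repository with Table-style per-(score x band) counts."""

    records: pd.DataFrame  # video_id, final_score, dba, band, included
    counts: pd.DataFrame  # index score 0..3, columns 75% / 100%
    n_total: int
    n_excluded: int

    @property
    def n_included(self) -> int:
        return self.n_total - self.n_excluded

    @property
    def exclusion_pct(self) -> float:
        """Percentage of videos excluded, rounded to two decimals."""
        if self.n_total == 0:
            return 0.0
        return round(100.0 * self.n_excluded / self.n_total, 2)

    def counts_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_json(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "exclusion_pct": self.exclusion_pct,
            "counts": {
                str(score): {band: int(self.counts.loc[score, band])
                             for band in self.counts.columns}
                for score in self.counts.index
            },
            "videos": [
                {
                    "video_id": row.video_id,
                    "final_score": None if pd.isna(row.final_score) else int(row.final_score),
                    "dba": None if pd.isna(row.dba) else float(row.dba),
                    "band": row.band,
                    "included": bool(row.included),
                }
                for row in self.records.itertuples()
            ],
        }


def _results_from(source, dba_mode: str, band_policy: str) -> list[ConsensusResult]:
    if isinstance(source, VoteTable):
        return score_videos(source, dba_mode=dba_mode, band_policy=band_policy)
    return list(source)


def build_repository(
    source: Union[VoteTable, Iterable[ConsensusResult]],
    manifest: Optional[Iterable] = None,
    dba_mode: str = "raw",
    band_policy: str = "out_of_range",
) -> Repository:
    """Assemble the filtered repository.

    ``source`` is either a :class:`VoteTable` (scored here) or a list of
    precomputed/transferred :class:`ConsensusResult`.  Videos with an
    unresolved majority or a band outside {75%, 100%} are excluded.
    ``manifest`` (optional) is an iterable of video records or ids; every
    assessed video must appear in it, and manifest videos without votes are
    carried as unassessed exclusions.
    """
    results = _results_from(source, dba_mode, band_policy)
    by_id: dict[str, ConsensusResult] = {}
    for res in results:
        if res.video_id in by_id:
            raise ValidationError(f"duplicate video id {res.video_id!r}")
        by_id[res.video_id] = res

    if manifest is not None:
        manifest_ids = []
        for rec in manifest:
            vid = rec if isinstance(rec, str) else getattr(rec, "video_id", None) or rec["video_id"]
            manifest_ids.append(str(vid))
        if len(set(manifest_ids)) != len(manifest_ids):
            raise ValidationError("duplicate video ids in manifest")
        unknown = set(by_id) - set(manifest_ids)
        if unknown:
            raise ValidationError(
                f"assessed videos missing from manifest: {sorted(unknown)[:5]}"
            )
        all_ids = manifest_ids
    else:
        all_ids = list(by_id)

    rows = []
    counts = pd.DataFrame(0, index=[0, 1, 2, 3], columns=["75%", "100%"])
    n_excluded = 0
    for vid in all_ids:
        res = by_id.get(vid)
        if res is None:
            rows.append((vid, np.nan, np.nan, "unassessed", False))
            n_excluded += 1
            continue
        included = res.accepted
        if included:
            counts.loc[res.final_score, res.band] += 1
        else:
            n_excluded += 1
        rows.append((vid, res.final_score, res.dba, res.band, included))

    records = pd.DataFrame(
        rows, columns=["video_id", "final_score", "dba", "band", "included"]
    )
    repo = Repository(
        records=records, counts=counts, n_total=len(all_ids), n_excluded=n_excluded
    )
    logger.info(
        "repository: %d/%d videos retained (%.2f%% excluded)",
        repo.n_included, repo.n_total, repo.exclusion_pct,
    )
    return repo


def transfer_scores(
    lateral: Sequence[ConsensusResult],
    pairing: Mapping[str, str],
    dorsal_ids: Optional[Iterable[str]] = None,
) -> list[ConsensusResult]:
    """Carry each resolved lateral score onto its paired dorsal video.

    ``pairing`` maps lateral ids to dorsal ids and must be injective; when
    ``dorsal_ids`` is given every mapped target must belong to it.
    Unpaired lateral videos are dropped with a logged warning.
    """
    targets = list(pairing.values())
    if len(set(targets)) != len(targets):
        raise ValidationError("pairing is not injective (two lateral ids share a dorsal id)")
    known_dorsal = set(dorsal_ids) if dorsal_ids is not None else None

    out = []
    for res in lateral:
        dorsal_id = pairing.get(res.video_id)
        if dorsal_id is None:
            logger.warning("lateral video %s has no dorsal pair; dropped", res.video_id)
            continue
        if known_dorsal is not None and dorsal_id not in known_dorsal:
            raise ValidationError(f"pairing target {dorsal_id!r} is not a known dorsal video")
        if not res.resolved:
            raise ValidationError(
                f"lateral video {res.video_id!r} is unresolved; cannot transfer"
            )
        out.append(
            ConsensusResult(
                video_id=dorsal_id,
                final_score=res.final_score,
                dba=res.dba,
                band=res.band,
            )
        )
    return out
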