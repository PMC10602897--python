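"""Pooled-screen depletion scoring from per-design read counts.

Guide cassettes are sequenced before (donor library) and after (host library)
transformation into the target organism; a guide that cuts well depletes its
host abundance.  Per sequencing run, a design's abundance is its perfect-read
count divided by the run's merged-pair total.  The average host abundance is
corrected for carry-over of untransformed donor plasmid using a spiked wash-
control sequence: the wash control's host abundance, scaled by the mass ratio
of DNA used to wash plasmid added (1 ug / 1 ng = 1000 by default), times the
design's donor abundance is subtracted (floored at zero).  The depletion
statistics are then

    delta      = corrected host abundance / average donor abundance
    log2delta  = log2(delta)

with a two-tailed heteroscedastic (Welch) t-test comparing the host vs donor
replicate abundance vectors.  Designs with fewer than 10 average donor reads
or p >= 0.05 go to the 'graveyard' and are excluded downstream; surviving
designs can be tail-labelled on log2delta for classification models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .forest import classify_tails

DEFAULT_MASS_RATIO = 1000.0  # 1 ug total DNA / 1 ng wash plasmid
MIN_DONOR_READS = 10.0
P_THRESHOLD = 0.05

KEPT = "kept"
GRAVEYARD = "graveyard"

COUNT_COLUMNS = ("design_id", "run_id", "library", "perfect_reads", "merged_pairs")
LIBRARIES = ("donor", "host")


class ScreenDataError(ValueError):
    """Malformed or inconsistent count data."""


@dataclass(frozen=True)
class DesignScore:
    """Depletion statistics for one design."""

    design_id: str
    avg_donor_reads: float
    avg_donor_abundance: float
    avg_host_abundance: float
    corrected_host_abundance: float
    delta: float
    log2delta: float
    p_value: float
    status: str
    reason: str = ""


def abundances(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-run abundances: perfect reads / merged pairs.

    Every included run must have a positive merged-pair total; zero perfect
    reads is a valid absent design (abundance 0), zero merged pairs is a data
    error.
    """
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ScreenDataError(f"count table missing column(s): {missing}")
    bad_lib = set(counts["library"]) - set(LIBRARIES)
    if bad_lib:
        raise ScreenDataError(f"unknown library label(s): {sorted(bad_lib)}")
    if (counts["perfect_reads"] < 0).any() or (counts["merged_pairs"] < 0).any():
        raise ScreenDataError("negative read counts")
    if (counts["perfect_reads"] > counts["merged_pairs"]).any():
        raise ScreenDataError("perfect reads exceed merged pairs")
    if (counts["merged_pairs"] == 0).any():
        zero = counts.loc[counts["merged_pairs"] == 0, ["design_id", "run_id"]]
        raise ScreenDataError(
            f"zero merged pairs in included run(s): {zero.values.tolist()[:5]}"
        )
    out = counts.copy()
    out["abundance"] = out["perfect_reads"] / out["merged_pairs"]
    return out


def wash_correction(
    host_avg: float,
    wash_host_abundance: float,
    donor_abundance: float,
    mass_ratio: float = DEFAULT_MASS_RATIO,
) -> float:
    """Wash-control corrected host abundance.

    ``host_avg - wash_host_abundance * mass_ratio * donor_abundance``, floored
    at zero (with a warning) since a physical abundance cannot be negative.
    """
    if min(host_avg, wash_host_abundance, donor_abundance, mass_ratio) < 0:
        raise ScreenDataError("wash-correction inputs must be non-negative")
    corrected = host_avg - wash_host_abundance * mass_ratio * donor_abundance
    if corrected < 0:
        warnings.warn(
            f"wash correction exceeds host abundance ({corrected:.3g}); floored at 0",
            stacklevel=2,
        )
        return 0.0
    return corrected


def welch_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-tailed unequal-variance (Welch) t-test p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ScreenDataError("Welch test needs >= 2 replicates per library")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate zero-variance case: identical means are maximally null
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def score_design(
    design_id: str,
    donor_reads: Sequence[float],
    donor_abundance: Sequence[float],
    host_abundance: Sequence[float],
    wash_host_abundance: float,
    mass_ratio: float = DEFAULT_MASS_RATIO,
) -> DesignScore:
    """Score one design from its replicate read/abundance vectors."""
    donor_ab = np.asarray(donor_abundance, dtype=float)
    host_ab = np.asarray(host_abundance, dtype=float)
    avg_donor_reads = float(np.mean(donor_reads))
    avg_donor = float(donor_ab.mean())
    avg_host = float(host_ab.mean())
    corrected = wash_correction(avg_host, wash_host_abundance, avg_donor, mass_ratio)

    reason = ""
    if avg_donor == 0:
        delta = np.nan
        log2delta = np.nan
        reason = "zero donor abundance; delta undefined"
    else:
        delta = corrected / avg_donor
        with np.errstate(divide="ignore"):
            log2delta = float(np.log2(delta)) if delta > 0 else -np.inf
    p_value = welch_p(host_ab, donor_ab)

    if avg_donor_reads < MIN_DONOR_READS:
        status, reason = GRAVEYARD, reason or f"avg donor reads < {MIN_DONOR_READS:g}"
    elif not (p_value < P_THRESHOLD):
        status, reason = GRAVEYARD, reason or f"p-value >= {P_THRESHOLD}"
    elif np.isnan(delta):
        status = GRAVEYARD
    else:
        status = KEPT
    return DesignScore(
        design_id=design_id,
        avg_donor_reads=avg_donor_reads,
        avg_donor_abundance=avg_donor,
        avg_host_abundance=avg_host,
        corrected_host_abundance=corrected,
        delta=float(delta),
        log2delta=float(log2delta),
        p_value=p_value,
        status=status,
        reason=reason,
    )


def score_screen(
    counts: pd.DataFrame,
    wash_id: str,
    mass_ratio: float = DEFAULT_MASS_RATIO,
) -> pd.DataFrame:
    """Score every design in a long-format count table.

    ``counts`` columns: design_id, run_id, library in {donor, host},
    perfect_reads, merged_pairs (one row per design per run).  ``wash_id``
    names the spiked wash-control design used for host correction.  Returns
    one scored row per non-control design, in first-appearance input order.
    """
    ab = abundances(counts)
    if wash_id not in set(ab["design_id"]):
        raise ScreenDataError(f"wash control {wash_id!r} not present in count table")
    wash_host = ab.loc[(ab["design_id"] == wash_id) & (ab["library"] == "host")]
    if len(wash_host) == 0:
        raise ScreenDataError(f"wash control {wash_id!r} has no host-library runs")
    wash_host_abundance = float(wash_host["abundance"].mean())

    rows = []
    for design_id in ab["design_id"].drop_duplicates():
        if design_id == wash_id:
            continue
        sub = ab[ab["design_id"] == design_id]
        donor = sub[sub["library"] == "donor"]
        host = sub[sub["library"] == "host"]
        if len(donor) < 2 or len(host) < 2:
            raise ScreenDataError(
                f"design {design_id!r} needs >= 2 donor and >= 2 host runs"
            )
        rows.append(
            score_design(
                design_id=design_id,
                donor_reads=donor["perfect_reads"].to_numpy(),
                donor_abundance=donor["abundance"].to_numpy(),
                host_abundance=host["abundance"].to_numpy(),
                wash_host_abundance=wash_host_abundance,
                mass_ratio=mass_ratio,
            ).__dict__
        )
    return pd.DataFrame(rows)


def filter_and_label(
    scores: pd.DataFrame, n_tail: int | None = None
) -> pd.DataFrame:
    """Drop graveyard designs; optionally tail-label the survivors.

    With ``n_tail`` the kept designs gain a ``label`` column: the ``n_tail``
    lowest log2delta values are class 0, the ``n_tail`` highest class 1, the
    middle NaN (excluded).
    """
    kept = scores.loc[scores["status"] == KEPT].reset_index(drop=True)
    if n_tail is not None:
        if 2 * n_tail > len(kept):
            raise ValueError(
                f"2*n_tail={2 * n_tail} exceeds the {len(kept)} kept designs"
            )
        kept = kept.copy()
        kept["label"] = classify_tails(kept["log2delta"].to_numpy(), n_tail)
    return kept
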