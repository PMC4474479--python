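"""Assay validation: Z'-factor analysis and dose-response characterization.

Z' = 1 - 3 * (sigma_p + sigma_n) / |mu_p - mu_n|

computed over per-well scores of the positive- and negative-control classes
(sample standard deviation, ddof=1).  Values near 1 indicate a large
separation band; 0.5 is commonly taken as the screening floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import WellQuant


class DegenerateAssayError(ValueError):
    """Positive and negative control means coincide: Z' is undefined."""


class InsufficientReplicatesError(ValueError):
    """Fewer than two wells in a control class."""


@dataclass(frozen=True)
class ZPrimeResult:
    mu_p: float
    mu_n: float
    sigma_p: float
    sigma_n: float
    zprime: float
    n_p: int
    n_n: int


def compute_zprime(neg_scores, pos_scores) -> ZPrimeResult:
    """Z' factor from per-well negative- and positive-control values."""
    neg = np.asarray(list(neg_scores), dtype=float)
    pos = np.asarray(list(pos_scores), dtype=float)
    if len(neg) < 2 or len(pos) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 wells per control class, got {len(neg)} negative / {len(pos)} positive"
        )
    mu_n, mu_p = float(neg.mean()), float(pos.mean())
    if mu_n == mu_p:
        raise DegenerateAssayError("control means are equal; the assay has no signal window")
    sigma_n = float(neg.std(ddof=1))
    sigma_p = float(pos.std(ddof=1))
    zprime = 1.0 - 3.0 * (sigma_p + sigma_n) / abs(mu_p - mu_n)
    return ZPrimeResult(
        mu_p=mu_p, mu_n=mu_n, sigma_p=sigma_p, sigma_n=sigma_n,
        zprime=zprime, n_p=len(pos), n_n=len(neg),
    )


@dataclass(frozen=True)
class DoseResponseRow:
    dose_gy: float
    timepoint_h: float
    mean_foci: float  # mean over wells of per-well mean foci/nucleus
    sd_foci: float  # SD across wells (NaN for a single well)
    fraction_gt20: float  # mean over wells
    n_wells: int


def dose_response(
    quants: list[WellQuant],
    conditions: dict[tuple[str, str], tuple[float, float]],
) -> list[DoseResponseRow]:
    """Group per-well quantities by (dose, time point).

    ``conditions`` maps (plate_id, well_id) to (dose_gy, timepoint_h) —
    typically built from a plate map.  Rows come back sorted by dose then
    time so the 2 h and 24 h series read off directly.
    """
    buckets: dict[tuple[float, float], list[WellQuant]] = {}
    for q in quants:
        if not q.usable:
            continue
        key = conditions.get((q.plate_id, q.well_id))
        if key is None:
            continue
        buckets.setdefault((float(key[0]), float(key[1])), []).append(q)
    rows = []
    for (dose, tp) in sorted(buckets):
        ws = buckets[(dose, tp)]
        means = np.array([w.mean_foci_per_nucleus for w in ws])
        fr20 = np.array([w.fraction_gt20 for w in ws])
        rows.append(
            DoseResponseRow(
                dose_gy=dose,
                timepoint_h=tp,
                mean_foci=float(means.mean()),
                sd_foci=float(means.std(ddof=1)) if len(ws) > 1 else float("nan"),
                fraction_gt20=float(fr20.mean()),
                n_wells=len(ws),
            )
        )
    return rows


def dose_response_frame(rows: list[DoseResponseRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dose_gy": r.dose_gy,
                "timepoint_h": r.timepoint_h,
                "mean_foci": r.mean_foci,
                "sd_foci": r.sd_foci,
                "fraction_gt20": r.fraction_gt20,
                "n_wells": r.n_wells,
            }
            for r in rows
        ]
    )


def plot_dose_response(rows: list[DoseResponseRow], path) -> None:
    """Two-panel dose-response figure: mean foci and % nuclei with >20 foci."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = dose_response_frame(rows)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for tp, grp in df.groupby("timepoint_h"):
        grp = grp.sort_values("dose_gy")
        axes[0].errorbar(grp["dose_gy"], grp["mean_foci"], yerr=grp["sd_foci"],
                         marker="o", capsize=3, label=f"{tp:g} h")
        axes[1].plot(grp["dose_gy"], 100 * grp["fraction_gt20"], marker="s", label=f"{tp:g} h")
    axes[0].set_xlabel("dose (Gy)")
    axes[0].set_ylabel("foci per nucleus")
    axes[1].set_xlabel("dose (Gy)")
    axes[1].set_ylabel("% nuclei with >20 foci")
    for ax in axes:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_zprime(result: ZPrimeResult, neg_scores, pos_scores, path) -> None:
    """Strip plot of control wells with the 3-sigma bands behind Z'."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    neg = np.asarray(list(neg_scores), dtype=float)
    pos = np.asarray(list(pos_scores), dtype=float)
    ax.plot(np.arange(len(neg)), neg, "o", label="negative (vehicle)")
    ax.plot(np.arange(len(pos)), pos, "s", label="positive control")
    for mu, sd, color in ((result.mu_n, result.sigma_n, "C0"), (result.mu_p, result.sigma_p, "C1")):
        ax.axhline(mu, color=color, lw=1)
        ax.axhspan(mu - 3 * sd, mu + 3 * sd, color=color, alpha=0.15)
    ax.set_xlabel("well index")
    ax.set_ylabel("normalized fold score")
    ax.set_title(f"Z' = {result.zprime:.3f}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
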