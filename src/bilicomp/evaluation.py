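"""Accuracy statistics: per-level summaries, pooled RMSE, Bland–Altman.

Estimates are compared with nominal concentrations as (nominal, estimate)
pairs.  Conventions:

* difference = estimate − nominal, so overestimation gives a positive bias
  (reports also show the opposite, nominal − estimate, for comparison with
  literature that uses it);
* per-level SD uses the sample (n−1) denominator, RMSE the n denominator,
  which gives the exact decomposition ``rmse² = bias² + sd²·(n−1)/n``;
* limits of agreement are ``bias ± 1.96·SD(differences)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .exceptions import DomainError

__all__ = [
    "LevelSummary",
    "AgreementStats",
    "ComparisonReport",
    "summarize_by_level",
    "pooled_rmse",
    "bland_altman",
    "compare_runs",
]

Pair = tuple[float, float]  # (nominal, estimate), both mg/dL

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class LevelSummary:
    """Estimate statistics at one nominal concentration level."""

    nominal: float
    mean_estimate: float
    sd_estimate: float  # sample SD (n−1); 0 with flag when n == 1
    rmse: float
    n: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman bias and limits of agreement (estimate − nominal)."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int


def _check_pairs(pairs: Sequence[Pair], min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    if len(pairs) < min_n:
        raise DomainError(f"need at least {min_n} (nominal, estimate) pairs, got {len(pairs)}")
    arr = np.asarray(pairs, dtype=float)
    return arr[:, 0], arr[:, 1]


def summarize_by_level(pairs: Sequence[Pair]) -> list[LevelSummary]:
    """Mean, sample SD and RMSE of estimates per nominal level, ascending."""
    nominal, est = _check_pairs(pairs, 1)
    out: list[LevelSummary] = []
    for level in np.unique(nominal):
        e = est[nominal == level]
        n = int(e.size)
        if n > 1:
            sd, flags = float(np.std(e, ddof=1)), ()
        else:
            sd, flags = 0.0, ("sd_undefined",)
        out.append(
            LevelSummary(
                nominal=float(level),
                mean_estimate=float(e.mean()),
                sd_estimate=sd,
                rmse=float(np.sqrt(np.mean((e - level) ** 2))),
                n=n,
                flags=flags,
            )
        )
    return out


def pooled_rmse(pairs: Sequence[Pair]) -> float:
    """Root-mean-square error over all tests, √(mean((estimate−nominal)²))."""
    nominal, est = _check_pairs(pairs, 1)
    return float(np.sqrt(np.mean((est - nominal) ** 2)))


def bland_altman(pairs: Sequence[Pair]) -> AgreementStats:
    """Bland–Altman agreement of estimates against nominal values.

    Differences are estimate − nominal; bias is their mean and the limits of
    agreement are bias ± 1.96 · sample SD of the differences.  (For plotting,
    the conventional x-coordinate is the pair mean (estimate + nominal)/2.)
    """
    nominal, est = _check_pairs(pairs, 2)
    diffs = est - nominal
    bias = float(diffs.mean())
    sd = float(np.std(diffs, ddof=1))
    return AgreementStats(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        n=int(diffs.size),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Side-by-side accuracy of non-compensated vs compensated estimates."""

    levels_noncomp: tuple[LevelSummary, ...]
    levels_comp: tuple[LevelSummary, ...]
    pooled_rmse_noncomp: float
    pooled_rmse_comp: float
    rmse_ratio: float  # compensated / non-compensated
    agreement_noncomp: AgreementStats
    agreement_comp: AgreementStats
    n: int

    def to_dict(self) -> dict:
        def ba(a: AgreementStats) -> dict:
            d = asdict(a)
            # opposite sign convention (nominal − estimate), for comparison
            # with reports that use it
            d["bias_nominal_minus_estimate"] = -a.bias
            return d

        return {
            "n": self.n,
            "pooled_rmse": {
                "non_compensated": self.pooled_rmse_noncomp,
                "compensated": self.pooled_rmse_comp,
                "ratio_comp_over_noncomp": self.rmse_ratio,
            },
            "bland_altman": {
                "non_compensated": ba(self.agreement_noncomp),
                "compensated": ba(self.agreement_comp),
            },
            "levels": [
                {
                    "nominal_mgdl": ln.nominal,
                    "non_compensated": {k: v for k, v in asdict(ln).items() if k != "nominal"},
                    "compensated": {k: v for k, v in asdict(lc).items() if k != "nominal"},
                }
                for ln, lc in zip(self.levels_noncomp, self.levels_comp)
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        """Fixed-width table: level, mean ± SD and RMSE for both arms."""
        lines = [
            f"{'Nominal':>9}  {'Non-compensated':>22}  {'RMSE':>6}  "
            f"{'Compensated':>22}  {'RMSE':>6}",
            f"{'[mg/dL]':>9}  {'mean ± SD [mg/dL]':>22}  {'':>6}  "
            f"{'mean ± SD [mg/dL]':>22}  {'':>6}",
            "-" * 75,
        ]
        for ln, lc in zip(self.levels_noncomp, self.levels_comp):
            lines.append(
                f"{ln.nominal:>9.2f}  "
                f"{f'{ln.mean_estimate:.2f} ± {ln.sd_estimate:.2f}':>22}  "
                f"{ln.rmse:>6.2f}  "
                f"{f'{lc.mean_estimate:.2f} ± {lc.sd_estimate:.2f}':>22}  "
                f"{lc.rmse:>6.2f}"
            )
        lines.append("-" * 75)
        lines.append(
            f"{'pooled':>9}  {'':>22}  {self.pooled_rmse_noncomp:>6.2f}  "
            f"{'':>22}  {self.pooled_rmse_comp:>6.2f}"
        )
        lines.append(
            f"RMSE ratio (comp/non-comp): {self.rmse_ratio:.3f}   n = {self.n}"
        )
        a, b = self.agreement_noncomp, self.agreement_comp
        lines.append(
            f"Bias (est − nominal): {a.bias:+.2f} → {b.bias:+.2f} mg/dL; "
            f"LoA non-comp [{a.loa_lower:+.2f}, {a.loa_upper:+.2f}], "
            f"comp [{b.loa_lower:+.2f}, {b.loa_upper:+.2f}]"
        )
        return "\n".join(lines)


def compare_runs(noncomp: Sequence[Pair], comp: Sequence[Pair]) -> ComparisonReport:
    """Compare non-compensated and compensated estimates on the same tests."""
    if len(noncomp) != len(comp):
        raise DomainError(
            f"mismatched test sets: {len(noncomp)} non-compensated vs "
            f"{len(comp)} compensated pairs"
        )
    nom_a = sorted(p[0] for p in noncomp)
    nom_b = sorted(p[0] for p in comp)
    if not np.allclose(nom_a, nom_b):
        raise DomainError("mismatched test sets: nominal concentrations differ")
    rmse_nc = pooled_rmse(noncomp)
    rmse_c = pooled_rmse(comp)
    return ComparisonReport(
        levels_noncomp=tuple(summarize_by_level(noncomp)),
        levels_comp=tuple(summarize_by_level(comp)),
        pooled_rmse_noncomp=rmse_nc,
        pooled_rmse_comp=rmse_c,
        rmse_ratio=rmse_c / rmse_nc if rmse_nc > 0 else math.nan,
        agreement_noncomp=bland_altman(noncomp),
        agreement_comp=bland_altman(comp),
        n=len(noncomp),
    )


def plot_bland_altman(
    noncomp: Sequence[Pair], comp: Sequence[Pair], path: str
) -> None:
    """Write a Bland–Altman plot of both arms to an image file.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for pairs, label, color, marker in (
        (noncomp, "non-compensated", "black", "D"),
        (comp, "compensated", "tab:blue", "o"),
    ):
        arr = np.asarray(pairs, dtype=float)
        mean = arr.mean(axis=1)
        diff = arr[:, 1] - arr[:, 0]
        stats = bland_altman(pairs)
        ax.scatter(mean, diff, s=18, label=label, color=color, marker=marker)
        ax.axhline(stats.bias, color=color, lw=1.5, ls="--")
        ax.axhline(stats.loa_lower, color=color, lw=0.8, ls=":")
        ax.axhline(stats.loa_upper, color=color, lw=0.8, ls=":")
    ax.set_xlabel("(estimate + nominal) / 2  [mg/dL]")
    ax.set_ylabel("estimate − nominal  [mg/dL]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
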