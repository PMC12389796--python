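"""Bounded interhemispheric asymmetry indices and their unstable precursors.

Both indices share the normalization

    f(a, b) = (a - b) / sqrt(2 (a^2 + b^2)),

which is bounded in [-1, 1] for all finite signed inputs (by the
Cauchy-Schwarz inequality, |a - b| <= sqrt(2) sqrt(a^2 + b^2), with
equality iff b = -a), preserves response polarity, and is defined to be 0
when both responses vanish.

* LC (laterality coefficient): a = response to one hand's motor imagery in
  the hemisphere contralateral to that hand, b = the ipsilateral
  (homotopic) channel's response.  One value per hand and symmetric pair.
* TRAC (task response asymmetry coefficient): a = one channel's response
  to contralateral-hand imagery, b = the same channel's response to
  ipsilateral-hand imagery.  One value per channel.

Earlier laterality normalizations from the fNIRS literature are provided
in reconstructed form for the numerical-stability comparison; each exhibits
a documented pathology when responses may be negative (polarity blindness,
hard saturation at +/-1 for opposite signs, or an unbounded value as the
denominator a + b approaches zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage_events import Montage

#: |a+b| below this (relative to scale) marks the ratio form as overflowed
_OVERFLOW_SENTINEL = np.inf

ALT_VARIANTS = ("eq1", "eq2", "eq3", "eq3_zeroed")


def _bounded_index(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("index inputs must be finite")
    denom = np.sqrt(2.0 * (a * a + b * b))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (a - b) / np.where(denom > 0, denom, 1.0), 0.0)
    # floating-point rounding can land an ulp outside the analytic bound
    out = np.clip(out, -1.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def lc(r_contra, r_ipsi):
    """Laterality coefficient (a - b)/sqrt(2(a^2 + b^2)), in [-1, 1].

    ``r_contra``/``r_ipsi`` are the signed GLM response amplitudes of the
    homotopic channel pair, contralateral and ipsilateral to the imagined
    hand.  Returns 0 when both responses are exactly zero.  Accepts scalars
    or arrays (elementwise).
    """
    return _bounded_index(r_contra, r_ipsi)


def trac(r_task_contra, r_task_ipsi):
    """Task response asymmetry coefficient; same form as :func:`lc`.

    ``r_task_contra``/``r_task_ipsi`` are one channel's signed response
    amplitudes to contralateral- and ipsilateral-hand motor imagery.
    """
    return _bounded_index(r_task_contra, r_task_ipsi)


def alt_laterality(a, b, variant: str):
    """Reconstructed earlier laterality normalizations (for comparison only).

    ``variant``:
      * ``eq1``: (|a| - |b|)/(|a| + |b|) - insensitive to response polarity;
      * ``eq2``: (a - b)/(|a| + |b|) - saturates at exactly +/-1 whenever
        the responses have opposite signs;
      * ``eq3``: (a - b)/(a + b) - unbounded as b -> -a;
      * ``eq3_zeroed``: eq3 after clamping negative inputs to 0.

    A vanishing denominator yields an overflow sentinel (signed infinity,
    or NaN at 0/0), never an exception; callers track these with
    ``overflow`` flags.
    """
    if variant not in ALT_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("index inputs must be finite")
    if variant == "eq3_zeroed":
        a = np.maximum(a, 0.0)
        b = np.maximum(b, 0.0)
        variant = "eq3"
    if variant == "eq1":
        num, den = np.abs(a) - np.abs(b), np.abs(a) + np.abs(b)
    elif variant == "eq2":
        num, den = a - b, np.abs(a) + np.abs(b)
    else:  # eq3
        num, den = a - b, a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
        out = np.where(
            den == 0, np.where(num == 0, np.nan, np.sign(num) * _OVERFLOW_SENTINEL), out
        )
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class StabilityReport:
    """Distributional summary of an index's absolute values."""

    frac_at_unity: float
    frac_above_099: float
    p95_abs: float
    max_abs: float
    n: int
    n_overflow: int = 0

    def __post_init__(self):
        if not (0 <= self.frac_at_unity <= 1 and 0 <= self.frac_above_099 <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.p95_abs > self.max_abs:
            raise ValueError("p95_abs cannot exceed max_abs")


def stability_report(values, overflow_flags=None, unity_tol: float = 1e-12) -> StabilityReport:
    """Summarize how often an index saturates or explodes.

    ``frac_at_unity`` counts |v| within ``unity_tol`` of 1; overflowed
    entries contribute +inf to ``max_abs`` and are reported separately.
    """
    v = np.abs(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("stability_report needs at least one value")
    if overflow_flags is not None:
        flags = np.asarray(overflow_flags, dtype=bool)
        v = np.where(flags, np.inf, v)
    n_over = int(np.sum(~np.isfinite(v)))
    # nearest-order-statistic percentile avoids interpolating with infinities
    method = "linear" if n_over == 0 else "nearest"
    p95 = float(np.percentile(v, 95, method=method))
    return StabilityReport(
        frac_at_unity=float(np.mean(np.abs(v - 1.0) <= unity_tol)),
        frac_above_099=float(np.mean(v > 0.99)),
        p95_abs=p95,
        max_abs=float(v.max()),
        n=int(v.size),
        n_overflow=n_over,
    )


def _contra_task(hemisphere: str, tasks: set[str]) -> tuple[str, str]:
    """(contra, ipsi) task labels for a channel in ``hemisphere``."""
    if {"mi_affected", "mi_intact"} <= tasks:
        # after mirroring, the lesioned hemisphere carries left labels and
        # the affected hand is contralateral to it
        return ("mi_affected", "mi_intact") if hemisphere == "left" else ("mi_intact", "mi_affected")
    return ("mi_right", "mi_left") if hemisphere == "left" else ("mi_left", "mi_right")


def compute_asymmetry_table(
    responses: pd.DataFrame,
    montage: Montage,
    index_kinds: tuple[str, ...] = ("LC", "TRAC"),
    alt_variants: tuple[str, ...] = (),
) -> pd.DataFrame:
    """LC per symmetric pair and hand, TRAC per channel, per chromophore.

    ``responses`` is a tidy (already mirrored, for patients) frame with
    columns ``channel, task, chromophore, coefficient`` plus any grouping
    columns among ``subject, session, day`` which are carried through.
    Units: LC rows carry ``unit = "<left>|<right>"`` (the pair) and
    ``index_kind`` of ``LC_<task>``; TRAC rows carry the channel and its
    hemisphere.  Requested ``alt_variants`` are evaluated on the same
    (contra, ipsi) wiring as LC, labeled ``alt_*`` with overflow flags.
    """
    group_cols = [c for c in ("subject", "session", "day") if c in responses.columns]
    mi_tasks = {t for t in responses["task"].unique() if str(t).startswith("mi_")}
    if not mi_tasks:
        raise ValueError("no motor-imagery task coefficients in responses")

    rows: list[dict] = []
    if group_cols:
        groups = responses.groupby(group_cols)
    else:
        groups = [((), responses)]
    for keys, grp in groups:
        if not isinstance(keys, tuple):
            keys = (keys,)
        base = dict(zip(group_cols, keys))
        for chrom, sub in grp.groupby("chromophore"):
            coefs: dict[tuple[str, str], float] = {
                (r.channel, r.task): r.coefficient
                for r in sub.itertuples()
                if r.task in mi_tasks
            }
            # LC (and alternatives): one value per pair and hand
            if "LC" in index_kinds or alt_variants:
                for lch, rch in montage.symmetric_pairs:
                    for task in sorted(mi_tasks):
                        # hemisphere contralateral to the imagined hand
                        if task == "mi_affected":
                            contra_hemi = "left"  # lesioned side after mirroring
                        elif task == "mi_intact":
                            contra_hemi = "right"
                        else:
                            contra_hemi = "right" if task == "mi_left" else "left"
                        contra_ch = lch if contra_hemi == "left" else rch
                        ipsi_ch = rch if contra_hemi == "left" else lch
                        if (contra_ch, task) not in coefs or (ipsi_ch, task) not in coefs:
                            continue
                        a, b = coefs[(contra_ch, task)], coefs[(ipsi_ch, task)]
                        unit = f"{lch}|{rch}"
                        if "LC" in index_kinds:
                            rows.append(
                                base | {
                                    "unit": unit, "hemisphere": "", "chromophore": chrom,
                                    "index_kind": f"LC_{task.removeprefix('mi_')}",
                                    "value": lc(a, b), "overflow": False,
                                }
                            )
                        for var in alt_variants:
                            v = alt_laterality(a, b, var)
                            rows.append(
                                base | {
                                    "unit": unit, "hemisphere": "", "chromophore": chrom,
                                    "index_kind": f"alt_{var}_{task.removeprefix('mi_')}",
                                    "value": v, "overflow": not np.isfinite(v),
                                }
                            )
            # TRAC: one value per paired channel
            if "TRAC" in index_kinds:
                for ch in montage.paired_channels:
                    hemi = montage.hemisphere_of_channel[ch]
                    contra_t, ipsi_t = _contra_task(hemi, mi_tasks)
                    if (ch, contra_t) not in coefs or (ch, ipsi_t) not in coefs:
                        continue
                    rows.append(
                        base | {
                            "unit": ch, "hemisphere": hemi, "chromophore": chrom,
                            "index_kind": "TRAC",
                            "value": trac(coefs[(ch, contra_t)], coefs[(ch, ipsi_t)]),
                            "overflow": False,
                        }
                    )
    return pd.DataFrame(rows)
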