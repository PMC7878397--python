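"""Two-step model of autophagosome turnover from four-condition LC3-II data.

The LC3 turnover assay measures LC3-II (a membrane-bound autophagosome
marker) under a 2x2 design: a control condition (EXP-) and one or more
stimulus conditions (EXP+), each with and without a lysosomal inhibitor
(BAF-, BAF+) such as bafilomycin.  Treating the autophagosome pool as a box
with an input (formation) and an output (degradation), and assuming the
basal condition is at equilibrium (basal formation = basal degradation),
the four lane values identify the model:

    pool_ss      = LC3-II(EXP-, BAF-)                 steady-state pool
    basal flux   = LC3-II(EXP-, BAF+) - LC3-II(EXP-, BAF-)
    degradation  = LC3-II(EXP+, BAF+) - LC3-II(EXP+, BAF-)   (conventional flux)
    formation    = LC3-II(EXP+, BAF+) - LC3-II(EXP-, BAF-)
    pool_t       = LC3-II(EXP+, BAF-) = pool_ss + formation - degradation

Condition ratios (EXP+/EXP-) for formation and degradation, and the net
turnover ratio degradation/formation (exactly 1 at basal equilibrium),
summarise whether a stimulus acts proportionally on both arms.

All quantities are amounts over the treatment window, in the arbitrary
units (au) of the chosen normalisation scheme; there is no per-hour
divisor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "LaneQuant",
    "FluxDesign",
    "FluxEstimates",
    "TurnoverRatios",
    "SCHEMES",
    "normalize",
    "basal_flux",
    "degradation_rate",
    "formation_rate",
    "compute_estimates",
    "turnover_ratios",
    "pool_balance",
    "summarize_estimates",
]

SCHEMES = ("lc3ii_over_control", "lc3ii_over_lc3i", "percent_over_control")

REFERENCE_CONDITION = "EXP-"


class DesignError(ValueError):
    """The replicate/condition/inhibitor table is incomplete or inconsistent."""


class SchemeError(ValueError):
    """Normalisation scheme cannot be applied to the provided lanes."""


@dataclass(frozen=True)
class LaneQuant:
    """One lane's band quantities plus its experimental factors.

    ``condition`` uses the reference level ``"EXP-"`` for control; treatment
    levels may be dose-labelled (e.g. ``"MRT_10uM"``).  ``inhibitor`` is True
    for lanes incubated with the lysosomal inhibitor (BAF+).
    """

    replicate_id: str
    condition: str
    inhibitor: bool
    lc3ii: float
    loading_control: float
    lc3i: float | None = None
    treatment_label: str = ""
    duration_h: float = 6.0

    def __post_init__(self) -> None:
        if self.loading_control <= 0:
            raise ValueError(
                f"lane ({self.replicate_id}, {self.condition}, BAF{'+' if self.inhibitor else '-'}): "
                f"loading control must be positive, got {self.loading_control}"
            )
        if self.lc3ii < 0:
            raise ValueError("LC3-II intensity cannot be negative")
        if self.lc3i is not None and self.lc3i < 0:
            raise ValueError("LC3-I intensity cannot be negative")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")


@dataclass
class FluxDesign:
    """Tidy table of normalised LC3-II values over the k x 2 x n design.

    ``data`` has columns ``replicate_id``, ``condition``, ``inhibitor``,
    ``value``; one row per lane.
    """

    data: pd.DataFrame
    scheme: str
    reference: tuple[str, bool] = (REFERENCE_CONDITION, False)

    def __post_init__(self) -> None:
        required = {"replicate_id", "condition", "inhibitor", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        dup = self.data.duplicated(["replicate_id", "condition", "inhibitor"])
        if dup.any():
            rows = self.data[dup][["replicate_id", "condition", "inhibitor"]]
            raise DesignError(f"duplicate design cells:\n{rows.to_string(index=False)}")

    @property
    def conditions(self) -> list[str]:
        ref = self.reference[0]
        others = sorted(c for c in self.data["condition"].unique() if c != ref)
        return [ref] + others if ref in set(self.data["condition"]) else others

    @property
    def replicates(self) -> list[str]:
        return sorted(self.data["replicate_id"].unique())

    def cell_matrix(self) -> pd.DataFrame:
        """Replicate x (condition, inhibitor) value matrix (NaN where absent)."""
        return self.data.pivot(
            index="replicate_id", columns=["condition", "inhibitor"], values="value"
        )

    def value(self, replicate_id: str, condition: str, inhibitor: bool) -> float:
        sel = self.data[
            (self.data["replicate_id"] == replicate_id)
            & (self.data["condition"] == condition)
            & (self.data["inhibitor"] == inhibitor)
        ]
        if len(sel) == 0:
            raise DesignError(
                f"missing design cell (condition={condition!r}, "
                f"BAF{'+' if inhibitor else '-'}) for replicate {replicate_id!r}"
            )
        return float(sel["value"].iloc[0])


@dataclass
class FluxEstimates:
    """Per-replicate, per-condition model estimates.

    ``data`` columns: replicate_id, condition, pool_ss, pool_t, basal_flux,
    formation, degradation, negative_rate_flag.
    """

    data: pd.DataFrame
    scheme: str
    reference: str = REFERENCE_CONDITION
    warnings: list[str] = field(default_factory=list)


@dataclass
class TurnoverRatios:
    """Per-replicate condition ratios vs the basal reference value of 1.

    ``data`` columns: replicate_id, condition, formation_ratio,
    degradation_ratio, net_ratio, undefined_flag.  The basal condition's net
    ratio is exactly 1 by the equilibrium assumption.
    """

    data: pd.DataFrame
    n_undefined: int = 0
    warnings: list[str] = field(default_factory=list)


def _lane_quotient(lane: LaneQuant, scheme: str) -> float:
    if scheme in ("lc3ii_over_control", "percent_over_control"):
        return lane.lc3ii / lane.loading_control
    if scheme == "lc3ii_over_lc3i":
        if lane.lc3i is None or lane.lc3i <= 0:
            raise SchemeError(
                f"lane ({lane.replicate_id}, {lane.condition}): scheme 'lc3ii_over_lc3i' "
                "requires a positive LC3-I value"
            )
        return lane.lc3ii / lane.lc3i
    raise SchemeError(f"unknown scheme {scheme!r}; choose one of {SCHEMES}")


def normalize(
    lanes: Iterable[LaneQuant],
    scheme: str = "lc3ii_over_control",
    reference: tuple[str, bool] = (REFERENCE_CONDITION, False),
) -> FluxDesign:
    """Normalise lane intensities into a :class:`FluxDesign`.

    ``lc3ii_over_control`` divides LC3-II by the loading control;
    ``lc3ii_over_lc3i`` divides by LC3-I; ``percent_over_control``
    additionally expresses each lane as a percentage of the same
    replicate's reference-cell quotient, so the reference cell averages
    100 by construction.
    """
    lanes = list(lanes)
    if not lanes:
        raise DesignError("no lanes provided")
    rows = [
        {
            "replicate_id": ln.replicate_id,
            "condition": ln.condition,
            "inhibitor": bool(ln.inhibitor),
            "value": _lane_quotient(ln, scheme),
        }
        for ln in lanes
    ]
    df = pd.DataFrame(rows)
    ref_cond, ref_inh = reference
    if scheme == "percent_over_control":
        ref_rows = df[(df["condition"] == ref_cond) & (df["inhibitor"] == ref_inh)]
        if ref_rows.empty:
            raise DesignError(
                f"reference cell (condition={ref_cond!r}, BAF{'+' if ref_inh else '-'}) is empty"
            )
        ref_by_rep = ref_rows.set_index("replicate_id")["value"]
        def to_percent(row):
            rep = row["replicate_id"]
            if rep not in ref_by_rep.index:
                raise DesignError(
                    f"replicate {rep!r} has no reference cell "
                    f"(condition={ref_cond!r}, BAF{'+' if ref_inh else '-'})"
                )
            return 100.0 * row["value"] / ref_by_rep.loc[rep]
        df["value"] = df.apply(to_percent, axis=1)
    return FluxDesign(data=df, scheme=scheme, reference=(ref_cond, ref_inh))


def basal_flux(design: FluxDesign) -> pd.Series:
    """Basal autophagic flux per replicate: (EXP-, BAF+) - (EXP-, BAF-).

    By the equilibrium assumption this single number is both the basal
    formation and the basal degradation.
    """
    return degradation_rate(design, design.reference[0])


def _cell(piv: pd.DataFrame, condition: str, inhibitor: bool) -> pd.Series:
    """One design cell per replicate, validated for presence."""
    key = (condition, inhibitor)
    label = f"(condition={condition!r}, BAF{'+' if inhibitor else '-'})"
    if key not in piv.columns:
        raise DesignError(f"missing design cell {label}")
    col = piv[key]
    if col.isna().any():
        rep = col.index[col.isna()][0]
        raise DesignError(f"missing design cell {label} for replicate {rep!r}")
    return col


def degradation_rate(design: FluxDesign, condition: str) -> pd.Series:
    """Degradation per replicate: (condition, BAF+) - (condition, BAF-).

    For any condition this equals the conventional autophagic flux.
    """
    piv = design.cell_matrix()
    out = _cell(piv, condition, True) - _cell(piv, condition, False)
    return out.rename("degradation")


def formation_rate(design: FluxDesign, condition: str) -> pd.Series:
    """Formation per replicate: (condition, BAF+) - (EXP-, BAF-).

    New autophagosomes made during the treatment window: the inhibitor-
    accumulated amount minus the steady-state pool of the same replicate.
    """
    piv = design.cell_matrix()
    out = _cell(piv, condition, True) - _cell(piv, design.reference[0], False)
    return out.rename("formation")


def _capped_warnings(messages: list[str], cap: int = 10) -> list[str]:
    if len(messages) <= cap:
        return messages
    return messages[:cap] + [f"... and {len(messages) - cap} more similar warnings"]


def compute_estimates(design: FluxDesign) -> FluxEstimates:
    """Evaluate all model quantities per replicate and condition.

    Negative rates are reported as-is with a warning flag (never clamped:
    clamping would bias the downstream ratio statistics); they typically
    indicate incomplete lysosomal inhibition or densitometry noise.
    """
    ref = design.reference[0]
    piv = design.cell_matrix()
    pool_ss = _cell(piv, ref, False)
    bf = _cell(piv, ref, True) - pool_ss
    warnings: list[str] = []
    frames = []
    for cond in design.conditions:
        acc = _cell(piv, cond, True)
        pool_t = _cell(piv, cond, False)
        form = acc - pool_ss
        degr = acc - pool_t
        neg = (form < 0) | (degr < 0)
        frames.append(
            pd.DataFrame(
                {
                    "replicate_id": piv.index,
                    "condition": cond,
                    "pool_ss": pool_ss.to_numpy(),
                    "pool_t": pool_t.to_numpy(),
                    "basal_flux": bf.to_numpy(),
                    "formation": form.to_numpy(),
                    "degradation": degr.to_numpy(),
                    "negative_rate_flag": neg.to_numpy(),
                }
            )
        )
        for rep in piv.index[neg]:
            warnings.append(
                f"negative rate for replicate {rep!r}, condition {cond!r} "
                f"(formation={form[rep]:.4g}, degradation={degr[rep]:.4g})"
            )
    data = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["replicate_id", "condition"], kind="stable")
        .reset_index(drop=True)
    )
    return FluxEstimates(
        data=data, scheme=design.scheme, reference=ref, warnings=_capped_warnings(warnings)
    )


def pool_balance(estimates: FluxEstimates) -> pd.Series:
    """Mass-balance residual pool_t - (pool_ss + formation - degradation).

    An algebraic identity of the estimators: must vanish (to rounding) for
    every replicate and condition; a nonzero residual indicates a pipeline
    defect, not a biological effect.
    """
    d = estimates.data
    res = d["pool_t"] - (d["pool_ss"] + d["formation"] - d["degradation"])
    res.name = "residual"
    return res


def turnover_ratios(estimates: FluxEstimates) -> TurnoverRatios:
    """Condition ratios (EXP+/EXP-) and net turnover ratio per replicate.

    The basal net ratio is returned as exactly 1 (forced by the
    equilibrium assumption).  Ratios with nonpositive denominators are
    flagged undefined (NaN) and counted, never silently dropped.
    """
    d = estimates.data
    ref = estimates.reference
    if ref not in set(d["condition"]):
        raise DesignError(f"basal condition {ref!r} absent from estimates")

    bf = d["basal_flux"].to_numpy()
    form = d["formation"].to_numpy()
    degr = d["degradation"].to_numpy()
    is_ref = (d["condition"] == ref).to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        fr = np.where(bf > 0, form / bf, np.nan)
        dr = np.where(bf > 0, degr / bf, np.nan)
        nr = np.where(form > 0, degr / form, np.nan)
    # forced by the equilibrium assumption: basal formation and degradation
    # are the same number, so every basal ratio is exactly 1
    fr[is_ref] = dr[is_ref] = nr[is_ref] = 1.0

    out = pd.DataFrame(
        {
            "replicate_id": d["replicate_id"],
            "condition": d["condition"],
            "formation_ratio": fr,
            "degradation_ratio": dr,
            "net_ratio": nr,
            "undefined_flag": np.isnan(fr) | np.isnan(dr) | np.isnan(nr),
        }
    )
    warnings: list[str] = []
    n_undef = 0
    for row in out[out["undefined_flag"]].itertuples():
        for name, val in (
            ("formation_ratio", row.formation_ratio),
            ("degradation_ratio", row.degradation_ratio),
            ("net_ratio", row.net_ratio),
        ):
            if math.isnan(val):
                n_undef += 1
                warnings.append(
                    f"replicate {row.replicate_id!r}, condition {row.condition!r}: "
                    f"{name} undefined (nonpositive denominator)"
                )
    basal_bad = d.loc[is_ref & (bf <= 0), "replicate_id"]
    for rep in basal_bad:
        warnings.append(
            f"replicate {rep!r}: nonpositive basal flux; condition ratios are undefined"
        )
    return TurnoverRatios(
        data=out, n_undefined=n_undef, warnings=_capped_warnings(warnings)
    )


def summarize_estimates(
    estimates: FluxEstimates, ratios: TurnoverRatios | None = None
) -> pd.DataFrame:
    """Mean ± SEM of every estimate (and ratio) per condition.

    Rates are computed per replicate first and summarised second, keeping
    the replicate pairing needed by the paired statistics downstream.
    """
    frames = [estimates.data]
    if ratios is not None:
        frames.append(ratios.data)
    merged = frames[0] if len(frames) == 1 else frames[0].merge(
        frames[1], on=["replicate_id", "condition"]
    )
    numeric = merged.select_dtypes(include=[np.number]).columns
    g = merged.groupby("condition")[list(numeric)]
    mean = g.mean().add_suffix("_mean")
    sem = g.sem().add_suffix("_sem")
    out = mean.join(sem)
    out["n"] = g.size()
    return out.reset_index()
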