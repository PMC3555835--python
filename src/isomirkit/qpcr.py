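"""RT-qPCR quantification: standard curves, geNorm stability, normalisation.

Quantities are taken from a calibration (standard) curve of Cq against
log10 relative input over a serial dilution series; amplification
efficiency is ``10^(-1/slope) - 1`` and a curve passes QC when the
efficiency lies in [90%, 110%] and r^2 >= 0.99.  Reference-miRNA
stability follows the geNorm M statistic: for reference j, the mean over
partners k of the standard deviation across samples of log2(q_j / q_k).
References with M below a threshold (1.5 by default) are retained and
their per-sample geometric mean forms the normalisation factor (NF);
target quantities are divided by the NF and expressed as fold change
relative to the lowest normalised value, then log2-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency (1.0 = perfect doubling per cycle)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def qc_pass(self) -> bool:
        return (
            self.slope < 0
            and 0.90 <= self.efficiency <= 1.10
            and self.r_squared >= 0.99
        )

    def quantity(self, cq: float) -> float:
        """Relative input quantity interpolated from the curve."""
        return 10.0 ** ((cq - self.intercept) / self.slope)


def fit_standard_curve(dilutions, cq_values) -> StandardCurve:
    """OLS fit of Cq on log10(relative input) over a dilution series.

    ``dilutions`` are relative input amounts (e.g. 1, 0.1, 0.01 for a
    10-fold series); at least three distinct levels are required.
    """
    d = np.asarray(dilutions, dtype=float)
    cq = np.asarray(cq_values, dtype=float)
    if d.shape != cq.shape:
        raise ValueError("dilutions and Cq values must align")
    if len(np.unique(d)) < 3:
        raise ValueError("need at least three dilution levels")
    if np.any(d <= 0):
        raise ValueError("dilutions must be positive")
    x = np.log10(d)
    if np.ptp(x) == 0:
        raise ValueError("dilutions have zero variance")
    fit = stats.linregress(x, cq)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


@dataclass
class GeNormResult:
    m_values: pd.Series  # stability M per reference
    retained: list[str]  # references with M below the threshold
    nf: pd.Series  # normalisation factor per sample

    def __post_init__(self) -> None:
        if not self.retained:
            raise ValueError("no reference passed the stability threshold")


def genorm_m(quantities: pd.DataFrame) -> pd.Series:
    """geNorm stability M for each reference (rows) across samples (columns).

    M_j = mean over k != j of SD_samples( log2(q_j / q_k) ), sample SD
    with n-1 degrees of freedom.
    """
    if quantities.shape[0] < 2 or quantities.shape[1] < 2:
        raise ValueError("need at least two references and two samples")
    if (quantities <= 0).any().any():
        raise ValueError("quantities must be strictly positive")
    logq = np.log2(quantities)
    refs = list(quantities.index)
    m = {}
    for j in refs:
        sds = [
            float((logq.loc[j] - logq.loc[k]).std(ddof=1)) for k in refs if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, name="M")


def genorm_stability(
    quantities: pd.DataFrame,
    m_threshold: float = 1.5,
    iterative: bool = False,
) -> GeNormResult:
    """Screen references by geNorm M and derive the normalisation factor.

    Default behaviour is a single-pass screen retaining references with
    M < ``m_threshold``.  ``iterative=True`` instead applies the original
    stepwise scheme: repeatedly drop the least stable reference (highest
    M) and recompute, until all remaining references pass or only two
    remain.  NF per sample is the geometric mean of retained references.
    """
    m = genorm_m(quantities)
    if iterative:
        current = list(quantities.index)
        while len(current) > 2:
            m_cur = genorm_m(quantities.loc[current])
            worst = m_cur.idxmax()
            if m_cur.max() < m_threshold:
                break
            current.remove(worst)
        retained = current
    else:
        retained = [r for r in quantities.index if m[r] < m_threshold]
    if not retained:
        raise ValueError("no reference passed the stability threshold")
    nf = pd.Series(
        stats.gmean(quantities.loc[retained], axis=0),
        index=quantities.columns,
        name="NF",
    )
    return GeNormResult(m_values=m, retained=retained, nf=nf)


def relative_expression(
    target_quantities: pd.Series, genorm: GeNormResult
) -> pd.DataFrame:
    """Normalise a target's per-sample quantities by the NF.

    Fold changes are taken relative to the lowest normalised value, so
    every FC >= 1 and exactly one sample sits at FC = 1 (up to ties).
    Returns columns: quantity, normalized, fc, log2_fc.
    """
    missing = [s for s in target_quantities.index if s not in genorm.nf.index]
    if missing:
        raise ValueError(f"no normalisation factor for samples {missing}")
    q = target_quantities.astype(float)
    norm = q / genorm.nf.loc[q.index]
    fc = norm / norm.min()
    return pd.DataFrame(
        {
            "quantity": q,
            "normalized": norm,
            "fc": fc,
            "log2_fc": np.log2(fc),
        }
    )


def analyze_cq_table(
    df: pd.DataFrame,
    references: list[str],
    m_threshold: float = 1.5,
) -> tuple[pd.DataFrame, GeNormResult, pd.DataFrame]:
    """Full quantification of a tidy Cq table.

    ``df`` needs columns ``sample``, ``assay``, ``Cq`` and, on
    calibration rows, a non-null ``dilution`` (relative input of the
    serial dilution); a ``replicate`` column is carried through if
    present.  Per assay, the dilution rows fit the standard curve and
    every non-dilution Cq is converted to a quantity from it.  Reference
    assays are screened with geNorm; targets are normalised by the NF and
    expressed relative to their lowest per-sample mean.  Returns
    (curve report, geNorm result, tidy long expression table ready for
    downstream analysis of variance).
    """
    required = {"sample", "assay", "Cq"}
    if not required <= set(df.columns):
        raise ValueError(f"Cq table needs columns {sorted(required)}")
    dil = df["dilution"] if "dilution" in df.columns else pd.Series(
        np.nan, index=df.index
    )
    curves: dict[str, StandardCurve] = {}
    curve_rows = []
    for assay, sub in df.groupby("assay"):
        cal = sub[dil.loc[sub.index].notna()]
        if cal.empty:
            raise ValueError(f"assay {assay!r} has no dilution rows")
        curve = fit_standard_curve(cal["dilution"], cal["Cq"])
        curves[assay] = curve
        curve_rows.append(
            {
                "assay": assay,
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r_squared": curve.r_squared,
                "efficiency": curve.efficiency,
                "qc_pass": curve.qc_pass,
            }
        )
    meas = df[dil.isna()].copy()
    meas["quantity"] = [
        curves[a].quantity(c) for a, c in zip(meas["assay"], meas["Cq"])
    ]
    # per-sample geometric-mean quantity per assay (replicates collapse here)
    qmat = (
        meas.assign(logq=np.log(meas["quantity"]))
        .pivot_table(index="assay", columns="sample", values="logq", aggfunc="mean")
        .pipe(np.exp)
    )
    missing = [r for r in references if r not in qmat.index]
    if missing:
        raise ValueError(f"reference assays missing from the table: {missing}")
    genorm = genorm_stability(qmat.loc[references], m_threshold)
    meas["normalized"] = meas["quantity"] / genorm.nf.loc[meas["sample"]].values
    out_rows = []
    for assay in qmat.index:
        if assay in references:
            continue
        sub = meas[meas["assay"] == assay].copy()
        floor = (qmat.loc[assay] / genorm.nf).min()
        sub["fc"] = sub["normalized"] / floor
        sub["log2_fc"] = np.log2(sub["fc"])
        out_rows.append(sub)
    expression = (
        pd.concat(out_rows, ignore_index=True) if out_rows else pd.DataFrame()
    )
    return pd.DataFrame(curve_rows), genorm, expression


def synthetic_curve(
    efficiency: float,
    intercept: float = 30.0,
    n_levels: int = 5,
    fold: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free dilution series at a given amplification efficiency.

    Useful for round-trip checks: fitting the returned series recovers
    ``efficiency`` exactly (slope = -1 / log10(1 + E)).
    """
    slope = -1.0 / np.log10(1.0 + efficiency)
    d = fold ** -np.arange(n_levels, dtype=float)
    cq = intercept + slope * np.log10(d)
    return d, cq
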