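"""Diagnostic validity, reliability, concordance and clinical-utility statistics.

Everything here derives from a 2x2 table crossing the database (index) remission
label against the chart-review (reference) label::

                         reference +   reference -
        index positive       tp            fp
        index negative       fn            tn

Two confidence-interval conventions are provided for the proportion-type
statistics (sensitivity, specificity, predictive values, error rates,
prevalence):

``standard``
    Wald interval ``p +/- z * sqrt(p(1-p)/m)`` with ``m`` the statistic's own
    denominator, ``p`` at full precision and ``z`` the exact normal quantile.

``as_published``
    The convention that replicates interval estimates as they are printed in
    validation studies of this kind: ``m`` is the *total* sample size, the
    point estimate is first rounded to the printed 0.1% precision (three
    decimals as a proportion) before entering both the centre and the standard
    error, and ``z = 1.96``.  This is a faithfulness feature for replication,
    not a recommendation; ``standard`` is the default everywhere.

Cohen's kappa uses the large-sample standard error
``sqrt(Po(1-Po)/n) / (1-Pe)`` (``kappa_se="simple"``), with the
Fleiss-Cohen-Everitt delta-method estimator available as
``kappa_se="fleiss"``.  Under ``as_published`` the simple SE is evaluated with
``Po`` and ``Pe`` rounded to three decimals.

The model/results pair :class:`RemissionAgreement` /
:class:`RemissionAgreementResults` packages the whole suite with a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .episodes import Label, RemissionCall
from .io import ReferenceAssessment

__all__ = [
    "Estimate",
    "ConfusionTable",
    "SampleSizeSpec",
    "confusion_table",
    "validity_measures",
    "likelihood_ratios",
    "cohen_kappa",
    "phi_coefficient",
    "cronbach_alpha_binary",
    "mcnemar_chi2",
    "binary_auc",
    "sample_size_prevalence",
    "prevalence_ci",
    "round_half_away",
    "RemissionAgreement",
    "RemissionAgreementResults",
]

CI_CONVENTIONS = ("standard", "as_published")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _z(alpha: float, ci_convention: str) -> float:
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if ci_convention == "as_published" and alpha == 0.05:
        return 1.96  # the tabulated value used in the replicated reports
    return float(sps.norm.ppf(1 - alpha / 2))


def _check_convention(ci_convention: str) -> None:
    if ci_convention not in CI_CONVENTIONS:
        raise ValueError(
            f"ci_convention must be one of {CI_CONVENTIONS}, got {ci_convention!r}"
        )


@dataclass(frozen=True)
class Estimate:
    """A point estimate with an optional two-sided confidence interval."""

    value: float
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def ci(self) -> tuple[float, float] | None:
        if self.ci_low is None or self.ci_high is None:
            return None
        return (self.ci_low, self.ci_high)

    def pct(self, ndigits: int = 1) -> float:
        """The value as a percentage rounded half away from zero."""
        return round_half_away(self.value * 100.0, ndigits)

    def ci_pct(self, ndigits: int = 1) -> tuple[float, float] | None:
        if self.ci is None:
            return None
        return (
            round_half_away(self.ci_low * 100.0, ndigits),
            round_half_away(self.ci_high * 100.0, ndigits),
        )


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts: index (rows, positive = remission call) vs reference (columns)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def discordant(self) -> int:
        return self.fp + self.fn

    def counts(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)

    def to_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand the table into paired 0/1 label vectors (index, reference)."""
        index = np.concatenate(
            [np.ones(self.tp + self.fp, dtype=int), np.zeros(self.fn + self.tn, dtype=int)]
        )
        reference = np.concatenate(
            [
                np.ones(self.tp, dtype=int),
                np.zeros(self.fp, dtype=int),
                np.ones(self.fn, dtype=int),
                np.zeros(self.tn, dtype=int),
            ]
        )
        return index, reference

    @classmethod
    def from_labels(
        cls, index: Sequence[int], reference: Sequence[int]
    ) -> "ConfusionTable":
        index = np.asarray(index, dtype=int)
        reference = np.asarray(reference, dtype=int)
        if index.shape != reference.shape:
            raise ValueError("index and reference label vectors differ in length")
        if not (np.isin(index, (0, 1)).all() and np.isin(reference, (0, 1)).all()):
            raise ValueError("labels must be binary 0/1")
        return cls(
            tp=int(((index == 1) & (reference == 1)).sum()),
            fp=int(((index == 1) & (reference == 0)).sum()),
            fn=int(((index == 0) & (reference == 1)).sum()),
            tn=int(((index == 0) & (reference == 0)).sum()),
        )


def confusion_table(
    calls: Iterable[RemissionCall],
    assessments: Iterable[ReferenceAssessment],
) -> ConfusionTable:
    """Cross evaluable remission calls against reference assessments.

    NOT_EVALUABLE calls are excluded.  A missing assessment for an evaluable
    patient is an error naming the patient; assessments without calls are
    ignored (the chart review may cover a superset).
    """
    ref = {a.patient_id: a.reference_remission for a in assessments}
    tp = fp = fn = tn = 0
    for call in calls:
        if call.label is Label.NOT_EVALUABLE:
            continue
        if call.patient_id not in ref:
            raise KeyError(
                f"no reference assessment for evaluable patient {call.patient_id!r}"
            )
        positive = call.label is Label.REMISSION
        if positive and ref[call.patient_id] == 1:
            tp += 1
        elif positive:
            fp += 1
        elif ref[call.patient_id] == 1:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp, fp, fn, tn)


def _wald(
    k: int, m: int, n_total: int, alpha: float, ci_convention: str
) -> Estimate | None:
    """Wald estimate of a proportion k/m under either CI convention.

    Returns None when the denominator is zero (the statistic is undefined).
    """
    if m == 0:
        return None
    p = k / m
    z = _z(alpha, ci_convention)
    if ci_convention == "as_published":
        centre = round_half_away(p, 3)
        se = math.sqrt(centre * (1.0 - centre) / n_total)
    else:
        centre = p
        se = math.sqrt(p * (1.0 - p) / m)
    lo = max(0.0, centre - z * se)
    hi = min(1.0, centre + z * se)
    return Estimate(p, lo, hi)


def validity_measures(
    table: ConfusionTable,
    ci_convention: str = "standard",
    alpha: float = 0.05,
) -> dict[str, Estimate | None]:
    """Sensitivity, specificity, predictive values and error rates with Wald CIs.

    The false-positive rate is 1 - sensitivity and the false-negative rate is
    1 - specificity (complements on the reference-positive and
    reference-negative margins).  Statistics with a zero denominator are
    returned as ``None`` (undefined), never as zero.
    """
    _check_convention(ci_convention)
    t = table
    pos, neg = t.tp + t.fn, t.tn + t.fp
    return {
        "sensitivity": _wald(t.tp, pos, t.n, alpha, ci_convention),
        "specificity": _wald(t.tn, neg, t.n, alpha, ci_convention),
        "ppv": _wald(t.tp, t.tp + t.fp, t.n, alpha, ci_convention),
        "npv": _wald(t.tn, t.tn + t.fn, t.n, alpha, ci_convention),
        "false_positive_rate": _wald(t.fn, pos, t.n, alpha, ci_convention),
        "false_negative_rate": _wald(t.fp, neg, t.n, alpha, ci_convention),
    }


def likelihood_ratios(table: ConfusionTable) -> tuple[float, float]:
    """Positive and negative likelihood ratios (PPR, NPR).

    PPR = S / (1 - Sp); NPR = (1 - S) / Sp.  A perfectly specific test gives an
    infinite PPR (returned as ``math.inf``), not an exception.
    """
    t = table
    pos, neg = t.tp + t.fn, t.tn + t.fp
    if pos == 0 or neg == 0:
        raise ValueError("likelihood ratios need both reference margins > 0")
    s = t.tp / pos
    sp = t.tn / neg
    ppr = math.inf if sp == 1.0 else s / (1.0 - sp)
    npr = math.inf if sp == 0.0 else (1.0 - s) / sp
    return ppr, npr


def _kappa_components(table: ConfusionTable) -> tuple[float, float, float]:
    t, n = table, table.n
    po = (t.tp + t.tn) / n
    pe = ((t.tp + t.fp) * (t.tp + t.fn) + (t.fn + t.tn) * (t.fp + t.tn)) / n**2
    if pe == 1.0:
        raise ValueError("kappa undefined: expected agreement is 1")
    return po, pe, (po - pe) / (1.0 - pe)


def _fleiss_se(table: ConfusionTable) -> float:
    """Fleiss-Cohen-Everitt large-sample SE of kappa (the delta-method ASE)."""
    t, n = table, table.n
    p = np.array([[t.tp, t.fp], [t.fn, t.tn]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = p[0, 0] + p[1, 1]
    pe = row @ col
    k = (po - pe) / (1.0 - pe)
    term1 = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - k)) ** 2 for i in range(2)
    )
    term2 = (1.0 - k) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    var = (term1 + term2 - (k - pe * (1.0 - k)) ** 2) / (n * (1.0 - pe) ** 2)
    return math.sqrt(max(var, 0.0))


def cohen_kappa(
    table: ConfusionTable,
    alpha: float = 0.05,
    ci_convention: str = "standard",
    kappa_se: str = "simple",
) -> Estimate:
    """Cohen's kappa for the 2x2 agreement table, with a large-sample CI."""
    _check_convention(ci_convention)
    if table.n < 2:
        raise ValueError("kappa needs n >= 2")
    po, pe, kappa = _kappa_components(table)
    z = _z(alpha, ci_convention)
    if kappa_se == "fleiss":
        se = _fleiss_se(table)
    elif kappa_se == "simple":
        if ci_convention == "as_published":
            po_r = round_half_away(po, 3)
            pe_r = round_half_away(pe, 3)
            se = math.sqrt(po_r * (1.0 - po_r) / table.n) / (1.0 - pe_r)
        else:
            se = math.sqrt(po * (1.0 - po) / table.n) / (1.0 - pe)
    else:
        raise ValueError(f"kappa_se must be 'simple' or 'fleiss', got {kappa_se!r}")
    lo = max(-1.0, kappa - z * se)
    hi = min(1.0, kappa + z * se)
    return Estimate(kappa, lo, hi)


def phi_coefficient(table: ConfusionTable) -> float:
    """Phi: the Pearson correlation of the two binary indicators."""
    t = table
    marg = [t.tp + t.fp, t.fn + t.tn, t.tp + t.fn, t.fp + t.tn]
    if any(m == 0 for m in marg):
        raise ValueError("phi undefined: a marginal count is zero")
    return (t.tp * t.tn - t.fp * t.fn) / math.sqrt(math.prod(marg))


def cronbach_alpha_binary(table: ConfusionTable) -> float:
    """Cronbach's alpha treating index and reference labels as two dichotomous items.

    alpha = 2 * (1 - (v1 + v2) / v_total) with population (1/n) variances.
    """
    t, n = table, table.n
    if n < 2:
        raise ValueError("alpha needs n >= 2")
    p1 = (t.tp + t.fp) / n  # index-positive rate
    p2 = (t.tp + t.fn) / n  # reference-positive rate
    v1 = p1 * (1.0 - p1)
    v2 = p2 * (1.0 - p2)
    if v1 == 0.0 or v2 == 0.0:
        raise ValueError("alpha undefined: an item has zero variance")
    cov = t.tp / n - p1 * p2
    v_total = v1 + v2 + 2.0 * cov
    return 2.0 * (1.0 - (v1 + v2) / v_total)


def mcnemar_chi2(
    table: ConfusionTable, continuity_correction: bool = False
) -> tuple[float, float]:
    """McNemar's chi-square for systematic disagreement, with its p-value.

    With no discordant pairs the statistic is 0 by convention (p = 1).
    """
    d = table.discordant
    if d == 0:
        return 0.0, 1.0
    c = 1.0 if continuity_correction else 0.0
    num = max(abs(table.fp - table.fn) - c, 0.0)
    chi2 = num**2 / d
    return chi2, float(sps.chi2.sf(chi2, df=1))


def binary_auc(table: ConfusionTable) -> float:
    """Trapezoidal AUC of a single-threshold binary test: (S + Sp) / 2."""
    t = table
    pos, neg = t.tp + t.fn, t.tn + t.fp
    if pos == 0 or neg == 0:
        raise ValueError("AUC needs both reference margins > 0")
    return (t.tp / pos + t.tn / neg) / 2.0


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design-stage spec: expected prevalence, CI half-width, two-sided alpha."""

    expected_prevalence: float
    precision: float
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.expected_prevalence < 1:
            raise ValueError("expected_prevalence must be in (0, 1)")
        if not 0 < self.precision < 1:
            raise ValueError("precision must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def required_n(self) -> int:
        return sample_size_prevalence(
            self.expected_prevalence, self.precision, self.alpha
        )


def sample_size_prevalence(
    expected_prevalence: float, precision: float, alpha: float = 0.05
) -> int:
    """n = ceil(z^2 p (1-p) / d^2) for estimating a prevalence to half-width d."""
    spec = SampleSizeSpec(expected_prevalence, precision, alpha)  # validates
    z = float(sps.norm.ppf(1 - spec.alpha / 2))
    p, d = spec.expected_prevalence, spec.precision
    return math.ceil(z**2 * p * (1.0 - p) / d**2)


def prevalence_ci(
    k: int, n: int, alpha: float = 0.05, ci_convention: str = "standard"
) -> Estimate:
    """Wald interval for a prevalence k/n, clamped to [0, 1]."""
    _check_convention(ci_convention)
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    est = _wald(k, n, n, alpha, ci_convention)
    assert est is not None
    return est


class RemissionAgreement:
    """Agreement model between database remission calls and chart review.

    Built from paired binary label vectors, a :class:`ConfusionTable`, or
    remission calls plus reference assessments.  ``fit()`` evaluates the whole
    validity / reliability / concordance / clinical-utility suite and returns a
    :class:`RemissionAgreementResults`.
    """

    def __init__(
        self,
        index: Sequence[int],
        reference: Sequence[int],
        *,
        n_not_evaluable: int = 0,
    ):
        self.table = ConfusionTable.from_labels(index, reference)
        self.n_not_evaluable = int(n_not_evaluable)

    @classmethod
    def from_table(cls, table: ConfusionTable, *, n_not_evaluable: int = 0):
        model = cls.__new__(cls)
        model.table = table
        model.n_not_evaluable = int(n_not_evaluable)
        return model

    @classmethod
    def from_calls(
        cls,
        calls: Sequence[RemissionCall],
        assessments: Sequence[ReferenceAssessment],
    ):
        table = confusion_table(calls, assessments)
        n_ne = sum(c.label is Label.NOT_EVALUABLE for c in calls)
        return cls.from_table(table, n_not_evaluable=n_ne)

    def fit(
        self,
        ci_convention: str = "standard",
        alpha: float = 0.05,
        kappa_se: str = "simple",
        continuity_correction: bool = False,
    ) -> "RemissionAgreementResults":
        _check_convention(ci_convention)
        t = self.table
        measures = validity_measures(t, ci_convention, alpha)
        ppr, npr = likelihood_ratios(t)
        mc_stat, mc_p = mcnemar_chi2(t, continuity_correction)
        return RemissionAgreementResults(
            model=self,
            table=t,
            ci_convention=ci_convention,
            alpha=alpha,
            sensitivity=measures["sensitivity"],
            specificity=measures["specificity"],
            ppv=measures["ppv"],
            npv=measures["npv"],
            false_positive_rate=measures["false_positive_rate"],
            false_negative_rate=measures["false_negative_rate"],
            kappa=cohen_kappa(t, alpha, ci_convention, kappa_se),
            phi=phi_coefficient(t),
            cronbach_alpha=cronbach_alpha_binary(t),
            auc=binary_auc(t),
            ppr=ppr,
            npr=npr,
            mcnemar_stat=mc_stat,
            mcnemar_pvalue=mc_p,
        )


@dataclass(frozen=True)
class RemissionAgreementResults:
    """Fitted agreement statistics with their confidence intervals."""

    model: RemissionAgreement
    table: ConfusionTable
    ci_convention: str
    alpha: float
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    false_positive_rate: Estimate
    false_negative_rate: Estimate
    kappa: Estimate
    phi: float
    cronbach_alpha: float
    auc: float
    ppr: float
    npr: float
    mcnemar_stat: float
    mcnemar_pvalue: float

    def to_dict(self) -> dict:
        """All statistics on the percentage scale used in printed reports."""
        def pct(est: Estimate | None) -> dict | None:
            if est is None:
                return None
            out = {"value": est.pct()}
            if est.ci is not None:
                lo, hi = est.ci_pct()
                out["ci"] = [lo, hi]
            return out

        return {
            "n": self.table.n,
            "counts": {
                "tp": self.table.tp,
                "fp": self.table.fp,
                "fn": self.table.fn,
                "tn": self.table.tn,
            },
            "n_not_evaluable": self.model.n_not_evaluable,
            "discordant": self.table.discordant,
            "ci_convention": self.ci_convention,
            "alpha": self.alpha,
            "sensitivity": pct(self.sensitivity),
            "specificity": pct(self.specificity),
            "ppv": pct(self.ppv),
            "npv": pct(self.npv),
            "false_positive_rate": pct(self.false_positive_rate),
            "false_negative_rate": pct(self.false_negative_rate),
            "kappa": pct(self.kappa),
            "phi": round_half_away(self.phi * 100.0),
            "cronbach_alpha": round_half_away(self.cronbach_alpha * 100.0),
            "auc": round_half_away(self.auc * 100.0),
            "ppr": None if math.isinf(self.ppr) else round_half_away(self.ppr, 1),
            "npr": None if math.isinf(self.npr) else round_half_away(self.npr, 1),
            "mcnemar_chi2": round_half_away(self.mcnemar_stat, 3),
            "mcnemar_pvalue": round_half_away(self.mcnemar_pvalue, 4),
        }

    def summary(self) -> str:
        """A printed-report style table of every statistic."""
        t = self.table
        conf = int(round((1 - self.alpha) * 100))
        lines = [
            "Remission-by-approximation vs reference criteria",
            "=" * 56,
            f"n = {t.n}   (TP {t.tp}, FP {t.fp}, FN {t.fn}, TN {t.tn};"
            f" discordant {t.discordant}; not evaluable {self.model.n_not_evaluable})",
            f"CI convention: {self.ci_convention}   alpha = {self.alpha}",
            "-" * 56,
            f"{'Statistic':<28}{'Value (%)':>10}  {conf}% CI",
        ]

        def row(name: str, est: Estimate | None):
            if est is None:
                lines.append(f"{name:<28}{'undef.':>10}")
                return
            ci = est.ci_pct()
            ci_txt = f"{ci[0]:.1f} - {ci[1]:.1f}" if ci else "---"
            lines.append(f"{name:<28}{est.pct():>10.1f}  {ci_txt}")

        row("Sensitivity", self.sensitivity)
        row("Specificity", self.specificity)
        row("Positive predictive value", self.ppv)
        row("Negative predictive value", self.npv)
        row("False positives", self.false_positive_rate)
        row("False negatives", self.false_negative_rate)
        lines.append(
            f"{'Cronbach alpha':<28}{round_half_away(self.cronbach_alpha * 100):>10.1f}  ---"
        )
        lines.append(f"{'Area under the curve':<28}{round_half_away(self.auc * 100):>10.1f}  ---")
        lines.append(
            f"{'McNemar chi2 (p)':<28}{round_half_away(self.mcnemar_stat, 3):>10.3f}"
            f"  p = {self.mcnemar_pvalue:.3f}"
        )
        lines.append(f"{'Pearson correlation (phi)':<28}{round_half_away(self.phi * 100):>10.1f}  ---")
        row("Cohen kappa", self.kappa)
        ppr_txt = "inf" if math.isinf(self.ppr) else f"{round_half_away(self.ppr, 1):.1f}"
        npr_txt = "inf" if math.isinf(self.npr) else f"{round_half_away(self.npr, 1):.1f}"
        lines.append(f"{'Positive probability ratio':<28}{ppr_txt:>10}  ---")
        lines.append(f"{'Negative probability ratio':<28}{npr_txt:>10}  ---")
        lines.append("=" * 56)
        return "\n".join(lines)
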