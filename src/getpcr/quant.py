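"""DDCt quantification of wild-type / variant allele fractions.

The estimator is the classic relative-quantification transform at 100%
amplification efficiency (one doubling per cycle):

    dCt   = mean(Ct_watch) - mean(Ct_ref)        per sample
    ddCt  = dCt_sample - dCt_reference_sample
    f     = 2 ** -ddCt                            clipped to [0, 1]

With a cut-spanning watching primer and an unedited reference sample, ``f``
is the wild-type fraction and ``1 - f`` the editing efficiency; with a
variant-specific primer and a 100%-variant standard, ``f`` is the
variant-allele fraction (HDR or base-editing efficiency).

"No amplification within 40 cycles" is carried as NaN and censored at cycle
40; a watch channel censored in every replicate reports below-detection
(fraction 0) rather than a numeric estimate.  Standard errors propagate from
replicate variances by the first-order delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    IncompleteAssayError,
    InsufficientReplicatesError,
    UndefinedCorrelationError,
    ValidationError,
)

WATCH = "watch"
REF = "ref"
CHANNELS = (WATCH, REF)
CT_MAX = 45.0
DEFAULT_CENSOR_CT = 40.0

REQUIRED_COLUMNS = ("sample_id", "assay_id", "channel", "replicate", "ct")
_KEY = ["sample_id", "assay_id", "channel", "replicate"]


class CtTable:
    """Long-format Ct measurements: one row per well.

    Columns: ``sample_id, assay_id, channel (watch|ref), replicate (>=1),
    ct`` (cycles in (0, 45], NaN = no amplification).  Duplicate
    (sample, assay, channel, replicate) keys are rejected.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"Ct table missing column(s): {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["assay_id"] = df["assay_id"].astype(str)
        df["channel"] = df["channel"].astype(str)
        try:
            df["replicate"] = df["replicate"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"replicate column must be integer: {exc}") from None
        df["ct"] = pd.to_numeric(df["ct"], errors="raise")

        bad_channel = sorted(set(df["channel"]) - set(CHANNELS))
        if bad_channel:
            raise ValidationError(f"unknown channel value(s) {bad_channel}; expected {CHANNELS}")
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be >= 1")
        numeric = df["ct"].dropna()
        if ((numeric <= 0) | (numeric > CT_MAX)).any():
            raise ValidationError(f"numeric Ct values must lie in (0, {CT_MAX}]")
        dup = df.duplicated(subset=_KEY)
        if dup.any():
            first = df.loc[dup, _KEY].iloc[0].tolist()
            raise ValidationError(f"duplicate (sample, assay, channel, replicate) key: {first}")
        self._df = df.reset_index(drop=True)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records) -> "CtTable":
        return cls(pd.DataFrame(list(records), columns=list(REQUIRED_COLUMNS)))

    @classmethod
    def concat(cls, tables) -> "CtTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))

    # -- access ------------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def samples(self) -> list[str]:
        return sorted(self._df["sample_id"].unique())

    @property
    def assays(self) -> list[str]:
        return sorted(self._df["assay_id"].unique())

    def select(self, sample_id: str | None = None, assay_id: str | None = None) -> "CtTable":
        df = self._df
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
        if assay_id is not None:
            df = df[df["assay_id"] == assay_id]
        out = object.__new__(CtTable)
        out._df = df.reset_index(drop=True)
        return out

    def cts(self, channel: str | None = None) -> np.ndarray:
        df = self._df
        if channel is not None:
            df = df[df["channel"] == channel]
        return df["ct"].to_numpy(dtype=float)


@dataclass(frozen=True)
class EfficiencyEstimate:
    """A DDCt fraction estimate for one (sample, assay).

    ``fraction`` is the fraction of template matched by the watching primer
    relative to the reference sample: the wild-type fraction for an indel
    assay, the variant-allele fraction for a variant assay.
    """

    sample_id: str
    assay_id: str
    fraction: float
    delta_delta_ct: float
    sem: float
    n_replicates: int
    clipped: bool = False
    below_detection: bool = False

    @property
    def wild_fraction(self) -> float:
        return self.fraction

    @property
    def variant_fraction(self) -> float:
        return self.fraction

    @property
    def edit_frequency(self) -> float:
        return 1.0 - self.fraction


def _channel_stats(table: CtTable, censor_at: float):
    """(mean, sem^2, n, all_censored) per channel for a single-assay slice."""
    df = table.df
    pairs = df[["sample_id", "assay_id"]].drop_duplicates()
    if len(pairs) == 0:
        raise IncompleteAssayError("empty Ct-table slice")
    if len(pairs) > 1:
        raise IncompleteAssayError(
            f"slice spans {len(pairs)} (sample, assay) pairs; pass one at a time"
        )
    out = {}
    for channel in CHANNELS:
        raw = table.cts(channel)
        if raw.size == 0:
            raise IncompleteAssayError(
                f"missing {channel!r} channel for sample "
                f"{pairs.iloc[0]['sample_id']!r} assay {pairs.iloc[0]['assay_id']!r}"
            )
        all_censored = bool(np.isnan(raw).all())
        vals = np.where(np.isnan(raw), censor_at, raw)
        n = vals.size
        sem_sq = float(np.var(vals, ddof=1) / n) if n > 1 else 0.0
        out[channel] = (float(vals.mean()), sem_sq, n, all_censored)
    sid = str(pairs.iloc[0]["sample_id"])
    aid = str(pairs.iloc[0]["assay_id"])
    return sid, aid, out


def _ddct_estimate(sample: CtTable, reference: CtTable, censor_at: float) -> EfficiencyEstimate:
    sid, aid, s = _channel_stats(sample, censor_at)
    _, _, r = _channel_stats(reference, censor_at)

    if s[WATCH][3]:  # every watch replicate censored: below the ~0.1% floor
        return EfficiencyEstimate(sid, aid, 0.0, math.inf, 0.0, s[WATCH][2],
                                  clipped=False, below_detection=True)

    dct_sample = s[WATCH][0] - s[REF][0]
    dct_ref = r[WATCH][0] - r[REF][0]
    ddct = dct_sample - dct_ref
    var_ddct = s[WATCH][1] + s[REF][1] + r[WATCH][1] + r[REF][1]

    raw = 2.0 ** (-ddct)
    clipped = raw < 0.0 or raw > 1.0
    frac = min(1.0, max(0.0, raw))
    sem = math.log(2.0) * raw * math.sqrt(var_ddct)  # delta method at the raw value
    return EfficiencyEstimate(sid, aid, frac, ddct, sem, s[WATCH][2], clipped=clipped)


def wild_fraction(sample: CtTable, wild_control: CtTable, *,
                  censor_at: float = DEFAULT_CENSOR_CT) -> EfficiencyEstimate:
    """Wild-type fraction of a sample versus an unedited (100% wild) control
    measured with the same cut-spanning assay.  ``edit_frequency`` on the
    returned estimate is the indel efficiency."""
    return _ddct_estimate(sample, wild_control, censor_at)


def variant_fraction(sample: CtTable, variant_standard: CtTable, *,
                     censor_at: float = DEFAULT_CENSOR_CT) -> EfficiencyEstimate:
    """Variant-allele fraction of a sample versus a 100%-variant standard
    (e.g. a variant plasmid) measured with the same variant-specific assay.
    ``variant_fraction`` on the returned estimate is the HDR / base-editing
    efficiency."""
    return _ddct_estimate(sample, variant_standard, censor_at)


def quantify_table(ct: CtTable, control_sample: str, *,
                   censor_at: float = DEFAULT_CENSOR_CT) -> list[EfficiencyEstimate]:
    """DDCt estimates for every (sample, assay) in a table against the named
    reference sample (wild control or variant standard, per assay design)."""
    if control_sample not in ct.samples:
        raise ValidationError(f"control sample {control_sample!r} not in table")
    out = []
    for assay in ct.assays:
        control = ct.select(sample_id=control_sample, assay_id=assay)
        for sample in ct.samples:
            if sample == control_sample:
                continue
            sl = ct.select(sample_id=sample, assay_id=assay)
            if len(sl) == 0:
                continue
            out.append(_ddct_estimate(sl, control, censor_at))
    return out


def efficiency_from_counts(count: int, total: int, mode: str = "indel") -> float:
    """Sequencing-read count formulas, in percent.

    ``indel`` mode takes the wild-type read count: ``(1 - wild/total) * 100``.
    ``variant`` mode takes the expected-variant read count:
    ``expected/total * 100``.
    """
    if total <= 0:
        raise ValidationError("total read count must be positive")
    if not 0 <= count <= total:
        raise ValidationError("count must lie in [0, total]")
    if mode == "indel":
        return (1.0 - count / total) * 100.0
    if mode == "variant":
        return count / total * 100.0
    raise ValidationError(f"mode must be 'indel' or 'variant', got {mode!r}")


@dataclass(frozen=True)
class GroupComparison:
    levene_statistic: float
    levene_p: float
    equal_variance: bool
    t_statistic: float
    p_value: float
    method: str


def compare_groups(values_a, values_b, *, alpha: float = 0.05) -> GroupComparison:
    """Two-tailed t-test gated by Levene's variance-equality test.

    When Levene's p >= ``alpha`` the pooled-variance t-test is used, otherwise
    Welch's unequal-variance form.  Both test statistics and p-values are
    reported.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            f"each group needs n >= 2 replicates (got {a.size} and {b.size})"
        )
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate constant groups: no dispersion information at all
        same = float(a[0] == b[0])
        return GroupComparison(0.0, 1.0, True,
                               0.0 if same else math.inf,
                               1.0 if same else 0.0, "pooled")
    lev_stat, lev_p = stats.levene(a, b)
    equal_var = bool(np.isnan(lev_p) or lev_p >= alpha)
    t_stat, p_val = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(float(lev_stat), float(lev_p), equal_var,
                           float(t_stat), float(p_val),
                           "pooled" if equal_var else "welch")


def correlate_strategies(values_a, values_b) -> tuple[float, float]:
    """Pearson correlation coefficient and two-tailed p-value between two
    quantification strategies measured on the same samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValidationError("vectors must have equal length")
    if a.size < 3:
        raise InsufficientReplicatesError("Pearson correlation needs n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
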