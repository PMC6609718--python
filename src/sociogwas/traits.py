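"""Growth-trait calculators for performance-tested pigs.

Six traits are analysed: average daily gain (ADG), age at 100 kg (D100),
backfat at 100 kg (B100), average daily feed intake (ADFI), feed conversion
ratio (FCR) and residual feed intake (RFI).  D100 and B100 standardise the
raw test-day records to a 100-kg body weight with sex-specific correction
factors used in pig breeding programmes; RFI is the feed intake left over
after regression-expected intake for growth, backfat and metabolic body
weight is removed.

All calculators are pure functions of a :class:`GrowthRecord`.  Body
weights are kg, backfat mm; the unit of ADG/ADFI (g/day or kg/day) is
declared once per dataset and never converted silently.  RFI is always
reported on the g/day scale — the scale on which its printed coefficients
weight backfat and metabolic weight against feed — with any kg/day input
converted explicitly, never implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GrowthRecord",
    "days_to_100kg",
    "backfat_at_100kg",
    "average_metabolic_weight",
    "residual_feed_intake",
    "adg_and_fcr",
    "compute_trait_table",
    "RFI_COEF_ADG",
    "RFI_COEF_BFT",
    "RFI_COEF_AMW",
]

# D100 correction-factor multipliers (test weight per test day scaled by these)
_D100_CF = {"male": 1.826040, "female": 1.714645}
# B100 correction factors: base / (base + slope * (test weight - 100))
_B100_CF = {"male": (12.402, 0.106530), "female": (13.706, 0.119624)}
# RFI = ADFI - 1.41*ADG - 2.83*BFT - 110.9*AMW   (g/day, mm, kg^0.6)
RFI_COEF_ADG = 1.41
RFI_COEF_BFT = 2.83
RFI_COEF_AMW = 110.9


@dataclass
class GrowthRecord:
    """One animal's summarised performance-test record.

    ``adg``/``adfi`` may be supplied directly (already averaged over the
    test) or left None to be derived from weights and feed.
    """

    animal_id: str
    sex: str  # "male" | "female"
    test_days: float
    test_weight: float
    test_bft: float | None = None  # backfat thickness at test, mm
    total_feed: float | None = None  # kg over the test period
    bw_start: float | None = None  # BW at test start, kg
    bw_end: float | None = None  # BW at test end, kg
    adg: float | None = None
    adfi: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unrecognised sex {self.sex!r} for {self.animal_id!r}")
        if self.test_days is not None and self.test_days <= 0:
            raise ValueError("test_days must be positive")


def days_to_100kg(record: GrowthRecord) -> float:
    """Age in days adjusted to a 100-kg body weight.

    D100 = test_days - (test_weight - 100)/CF with
    CF = (test_weight/test_days) * 1.826040 (male) or 1.714645 (female).
    """
    if record.test_weight is None or record.test_weight <= 0:
        raise ValueError("test_weight must be positive")
    cf = (record.test_weight / record.test_days) * _D100_CF[record.sex]
    return record.test_days - (record.test_weight - 100.0) / cf


def backfat_at_100kg(record: GrowthRecord) -> float:
    """Backfat (mm) adjusted to a 100-kg body weight.

    B100 = BFT * CF with CF = base/(base + slope*(test_weight - 100)),
    base/slope = 12.402/0.106530 (male), 13.706/0.119624 (female).
    """
    if record.test_bft is None:
        raise ValueError("test_bft missing")
    base, slope = _B100_CF[record.sex]
    denom = base + slope * (record.test_weight - 100.0)
    if denom <= 0:
        raise ValueError(
            f"B100 correction undefined: test weight {record.test_weight} kg is out of range"
        )
    return record.test_bft * (base / denom)


def average_metabolic_weight(record: GrowthRecord) -> float:
    """Mean metabolic body weight over the test, kg^0.6.

    AMW = (BW2^1.6 - BW1^1.6) / (1.6 * (BW2 - BW1)), the exact average of
    BW^0.6 along a linear weight trajectory; lies strictly between
    BW1^0.6 and BW2^0.6.
    """
    b1, b2 = record.bw_start, record.bw_end
    if b1 is None or b2 is None or b1 <= 0:
        raise ValueError("bw_start and bw_end required, bw_start > 0")
    if b2 == b1:
        raise ValueError("degenerate test period: bw_end equals bw_start")
    if b2 < b1:
        raise ValueError("bw_end must exceed bw_start")
    return (b2**1.6 - b1**1.6) / (1.6 * (b2 - b1))


def residual_feed_intake(record: GrowthRecord, amw: float | None = None,
                         feed_unit: str = "kg") -> float:
    """RFI = ADFI - 1.41 ADG - 2.83 BFT - 110.9 AMW, on the g/day scale.

    The printed coefficients weight backfat (mm) and metabolic weight
    (kg^0.6) against feed and gain expressed in g/day — the scale on which
    residual feed intake is reported for this kind of performance test.
    ``feed_unit`` declares the scale of the record's adfi/adg ("kg" per day
    gets converted to g/day explicitly; "g" is used as is).
    """
    adg = record.adg
    adfi = record.adfi
    if adg is None or adfi is None or record.test_bft is None:
        raise ValueError("RFI needs adfi, adg and test_bft")
    if feed_unit not in ("kg", "g"):
        raise ValueError("feed_unit must be 'kg' or 'g'")
    if feed_unit == "kg":
        adfi, adg = 1000.0 * adfi, 1000.0 * adg
    if amw is None:
        amw = average_metabolic_weight(record)
    return adfi - RFI_COEF_ADG * adg - RFI_COEF_BFT * record.test_bft - RFI_COEF_AMW * amw


def adg_and_fcr(record: GrowthRecord) -> tuple[float, float]:
    """ADG = (BW2 - BW1)/test_days; FCR = ADFI/ADG."""
    if record.bw_start is None or record.bw_end is None:
        raise ValueError("adg needs bw_start and bw_end")
    adg = (record.bw_end - record.bw_start) / record.test_days
    adfi = record.adfi
    if adfi is None:
        if record.total_feed is None:
            raise ValueError("fcr needs adfi or total_feed")
        adfi = record.total_feed / record.test_days
    if adg == 0:
        raise ZeroDivisionError("FCR undefined at zero gain")
    return adg, adfi / adg


def compute_trait_table(records: pd.DataFrame, adg_unit: str = "kg") -> pd.DataFrame:
    """Compute the six-trait table from raw records.

    ``records`` columns: animal_id, sex, test_days, test_weight, test_bft,
    total_feed, bw_start, bw_end (adg/adfi optional).  ``adg_unit``
    declares the scale of the ADG/ADFI columns, both as supplied and as
    emitted ("kg" per day or "g" per day); RFI is always reported on the
    g/day scale of its printed coefficients.

    Missing backfat or feed excludes an animal from RFI/FCR (NaN) but not
    from ADG/D100; out-of-range records likewise yield NaN rather than
    dropping the row.
    """
    if adg_unit not in ("kg", "g"):
        raise ValueError("adg_unit must be 'kg' or 'g'")
    scale = 1.0 if adg_unit == "kg" else 1000.0
    rows = []
    for rec in records.itertuples(index=False):
        adg_in = _opt(rec, "adg")
        adfi_in = _opt(rec, "adfi")
        r = GrowthRecord(
            animal_id=str(rec.animal_id),
            sex=str(rec.sex),
            test_days=float(rec.test_days),
            test_weight=float(rec.test_weight),
            test_bft=_opt(rec, "test_bft"),
            total_feed=_opt(rec, "total_feed"),
            bw_start=_opt(rec, "bw_start"),
            bw_end=_opt(rec, "bw_end"),
            adg=None if adg_in is None else adg_in / scale,  # internal kg/day
            adfi=None if adfi_in is None else adfi_in / scale,
        )
        out = {"animal_id": r.animal_id, "sex": r.sex}
        try:
            adg, fcr = adg_and_fcr(r) if r.adg is None else (r.adg, None)
            if fcr is None:
                adfi = r.adfi if r.adfi is not None else (
                    r.total_feed / r.test_days if r.total_feed is not None else None
                )
                fcr = adfi / adg if (adfi is not None and adg != 0) else float("nan")
        except (ValueError, ZeroDivisionError):
            adg, fcr = float("nan"), float("nan")
        adfi = r.adfi
        if adfi is None and r.total_feed is not None:
            adfi = r.total_feed / r.test_days
        out["adg"] = adg * scale if adg == adg else adg
        out["adfi"] = adfi * scale if adfi is not None else float("nan")
        out["fcr"] = fcr
        out["d100"] = days_to_100kg(r)
        try:
            out["b100"] = backfat_at_100kg(r)
        except ValueError:
            out["b100"] = float("nan")
        try:
            r_kg = GrowthRecord(
                r.animal_id, r.sex, r.test_days, r.test_weight, r.test_bft,
                r.total_feed, r.bw_start, r.bw_end, adg, adfi,
            )
            out["rfi"] = residual_feed_intake(r_kg)
        except (ValueError, ZeroDivisionError):
            out["rfi"] = float("nan")
        rows.append(out)
    return pd.DataFrame(rows)


def _opt(rec, name):
    v = getattr(rec, name, None)
    if v is None:
        return None
    v = float(v)
    return None if v != v else v
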