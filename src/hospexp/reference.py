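"""Published reference values for validation and growth/ratio analytics.

These are the printed municipal yearbook statistics for Shanghai public
hospitals (2011-2016 per-capita outpatient/inpatient expenses with annual
growth rates), together with the published validation table
(simulated-vs-actual 2015/2016) and the published baseline three-year run of
the calibrated reference model.  They are *inputs* to the analytics — the
arithmetic (growth rates, percent differences, component ratios) is always
recomputed by this package, never copied.

Known inconsistencies in the published tables (each flagged where used):

* outpatient growth 2013/2014 print 4.1/4.4 but recompute from the adjacent
  per-capita values as 3.8/4.7 — the two printed values appear transposed;
* the 2015 inpatient-medicine-ratio validation row prints a difference of
  1.7% where its own simulated/actual pair (37.0 vs 34.1) recomputes as 8.5%;
* the baseline year-1 inpatient medicine ratio prints 37.0% where
  5382.1/15789.0 recomputes as 34.1% (years 2-3 are self-consistent).
"""

from __future__ import annotations

from typing import Dict, Tuple

# ---------------------------------------------------------------------------
# Per-capita medical expenses in public hospitals, 2011-2016 (CNY), with the
# published annual growth rates (%).
# ---------------------------------------------------------------------------

OUTPATIENT_PER_CAPITA: Dict[int, float] = {
    2011: 252.8, 2012: 265.9, 2013: 276.0, 2014: 289.0, 2015: 306.9, 2016: 330.2,
}
INPATIENT_PER_CAPITA: Dict[int, float] = {
    2011: 12_897.7, 2012: 13_498.2, 2013: 14_243.2, 2014: 14_862.2,
    2015: 15_935.7, 2016: 16_942.5,
}
PUBLISHED_GROWTH_OUTPATIENT: Dict[int, float] = {
    2012: 5.2, 2013: 4.1, 2014: 4.4, 2015: 6.2, 2016: 7.6,
}
PUBLISHED_GROWTH_INPATIENT: Dict[int, float] = {
    2012: 4.7, 2013: 5.5, 2014: 4.3, 2015: 7.2, 2016: 6.3,
}
#: Outpatient growth cells whose printed values are inconsistent with the
#: printed per-capita series (they appear transposed); recomputation gives
#: 2013 -> 3.8 and 2014 -> 4.7.
INCONSISTENT_GROWTH_CELLS: Tuple[Tuple[str, int], ...] = (("outpatient", 2013), ("outpatient", 2014))

# ---------------------------------------------------------------------------
# Validation table: metric -> year -> (simulated, actual, published diff %).
# Ratio metrics are in percent.
# ---------------------------------------------------------------------------

VALIDATION_TABLE: Dict[str, Dict[int, Tuple[float, float, float]]] = {
    "outpatient_total": {2015: (304.2, 306.9, -0.9), 2016: (311.0, 330.2, -5.8)},
    "outpatient_medicine": {2015: (176.5, 168.5, 4.7), 2016: (178.1, 173.0, 2.9)},
    "outpatient_exam": {2015: (35.6, 34.4, 3.5), 2016: (36.4, 39.0, -6.7)},
    "outpatient_medicine_ratio": {2015: (58.0, 54.9, 5.6), 2016: (57.3, 52.4, 9.4)},
    "outpatient_exam_ratio": {2015: (11.7, 11.2, 4.5), 2016: (11.7, 11.8, -0.8)},
    "inpatient_total": {2015: (15_789.0, 15_935.7, -0.9), 2016: (15_487.4, 16_942.5, -8.6)},
    "inpatient_medicine": {2015: (5382.1, 5523.7, -2.6), 2016: (5166.4, 5584.0, -7.5)},
    "inpatient_exam": {2015: (1005.3, 933.9, 7.6), 2016: (1019.1, 1033.1, -1.4)},
    "inpatient_medicine_ratio": {2015: (37.0, 34.1, 1.7), 2016: (33.4, 33.0, 1.2)},
    "inpatient_exam_ratio": {2015: (6.4, 5.9, 8.5), 2016: (6.6, 6.1, 8.2)},
}
#: The one validation cell whose published difference (1.7%) does not follow
#: from its own printed pair (37.0 vs 34.1 -> 8.5%).
INCONSISTENT_VALIDATION_CELLS: Tuple[Tuple[str, int], ...] = (("inpatient_medicine_ratio", 2015),)

# ---------------------------------------------------------------------------
# Published baseline three-year run of the calibrated reference model:
# metric -> (year 1, year 2, year 3).  Ratios/shares/rates in percent.
# ---------------------------------------------------------------------------

BASELINE_RUN: Dict[str, Tuple[float, float, float]] = {
    "outpatient_total": (304.2, 311.0, 314.5),
    "outpatient_medicine": (176.5, 178.1, 176.1),
    "outpatient_exam": (35.6, 36.4, 37.4),
    "outpatient_medicine_ratio": (58.0, 57.3, 56.0),
    "outpatient_exam_ratio": (11.7, 11.7, 11.9),
    "inpatient_total": (15_789.0, 15_487.4, 14_662.1),
    "inpatient_medicine": (5382.1, 5166.4, 4753.9),
    "inpatient_exam": (1005.3, 1019.1, 1033.8),
    "inpatient_medicine_ratio": (37.0, 33.4, 32.4),
    "inpatient_exam_ratio": (6.4, 6.6, 7.1),
    "subsidy_proportion_tertiary_comprehensive": (6.2, 6.2, 6.2),
    "subsidy_proportion_specialized": (9.3, 9.2, 9.1),
    "subsidy_proportion_district_hospital": (9.7, 9.7, 9.7),
    "subsidy_proportion_community_center": (15.2, 15.6, 16.3),
    "patient_share_tertiary_comprehensive": (40.2, 40.2, 40.2),
    "patient_share_specialized": (1.9, 2.0, 1.9),
    "patient_share_district_hospital": (44.0, 44.0, 44.0),
    "patient_share_community_center": (13.8, 13.9, 14.0),
    "overprescription_rate": (50.0, 50.2, 50.0),
}
#: Ratio cells of the baseline run that can be recomputed from their printed
#: component/total pairs: (ratio metric, component metric, total metric).
BASELINE_RATIO_DEFS: Tuple[Tuple[str, str, str], ...] = (
    ("outpatient_medicine_ratio", "outpatient_medicine", "outpatient_total"),
    ("outpatient_exam_ratio", "outpatient_exam", "outpatient_total"),
    ("inpatient_medicine_ratio", "inpatient_medicine", "inpatient_total"),
    ("inpatient_exam_ratio", "inpatient_exam", "inpatient_total"),
)
#: The one baseline ratio cell inconsistent with its printed pair
#: (year index 0; recomputes as 34.1).
INCONSISTENT_BASELINE_RATIO_CELLS: Tuple[Tuple[str, int], ...] = (("inpatient_medicine_ratio", 0),)
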