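"""Published aggregate counts of the three SMO cohort studies.

These are the cohort-level numbers reported when the WHO Maternal Near Miss
tool was applied retrospectively to three severe-maternal-outcome cohorts:
the Dutch nationwide LEMMoN study ("NL", high resource, n = 2538 after
exclusions), the Tanzanian Haydom Lutheran Hospital study ("TZ", low
resource, n = 248) and the Malawian Thyolo District 4M study ("MW", low
resource, n = 386). The raw patient-level data were never deposited; these
aggregates are the only public record and serve three purposes here:

* inputs to the worked examples that re-derive pooled detection rates,
  corrected life-threatening counts and case fatality rates;
* calibration targets for the synthetic cohort presets
  (:func:`nearmiss.simulate.preset_specs`);
* fixtures for the between-cohort significance tests.

All dictionaries are keyed by cohort id ``"NL"`` / ``"TZ"`` / ``"MW"``.
"""

from __future__ import annotations

from types import MappingProxyType

__all__ = [
    "COHORTS",
    "COHORT_N",
    "SETTINGS",
    "GROUP_DETECTION",
    "CORRECTED_LIFE_THREATENING",
    "DEATHS",
    "LIFE_THREATENING_DEATHS",
    "DEATHS_WITHOUT_ORGAN_DYSFUNCTION",
    "POTENTIALLY_LIFE_THREATENING_CFR",
    "EVENT_COUNTS",
    "AGE_BAND_COUNTS",
    "PARITY_BAND_COUNTS",
    "UNITS_BAND_COUNTS",
    "DATA_AVAILABLE",
    "AVAILABLE_INTERVENTIONS",
    "EXCLUDED_INSUFFICIENT_DATA",
]

COHORTS: tuple[str, ...] = ("NL", "TZ", "MW")

#: Women analysed per cohort (NL after excluding 14 cases with insufficient data).
COHORT_N = MappingProxyType({"NL": 2538, "TZ": 248, "MW": 386})

EXCLUDED_INSUFFICIENT_DATA = MappingProxyType({"NL": 14, "TZ": 0, "MW": 0})

SETTINGS = MappingProxyType(
    {"NL": "high_resource", "TZ": "low_resource", "MW": "low_resource"}
)

#: Women fulfilling >= 1 criterion per WHO criteria group.
GROUP_DETECTION = MappingProxyType(
    {
        "A": MappingProxyType({"NL": 2308, "TZ": 123, "MW": 336}),
        "B": MappingProxyType({"NL": 2116, "TZ": 231, "MW": 175}),
        "C": MappingProxyType({"NL": 1024, "TZ": 103, "MW": 84}),
    }
)

#: Life-threatening women after additionally counting every low-resource
#: woman transfused >= 1 unit (the "corrected" analysis).
CORRECTED_LIFE_THREATENING = MappingProxyType({"NL": 1024, "TZ": 228, "MW": 206})

#: Maternal deaths per cohort (whole study population).
DEATHS = MappingProxyType({"NL": 48, "TZ": 32, "MW": 46})

#: Maternal deaths within the (uncorrected) life-threatening population.
LIFE_THREATENING_DEATHS = MappingProxyType({"NL": 31, "TZ": 32, "MW": 21})

#: Deaths in which no organ-dysfunction criterion could be identified.
DEATHS_WITHOUT_ORGAN_DYSFUNCTION = MappingProxyType({"NL": 17, "TZ": 0, "MW": 15})

#: (deaths, n) among women fulfilling disease-based criteria only
#: ("potentially life-threatening phase").
POTENTIALLY_LIFE_THREATENING_CFR = MappingProxyType(
    {"NL": (23, 2308), "TZ": (13, 123), "MW": (35, 336)}
)

#: Events per WHO subcategory (one event = one met criterion for one woman).
#: ``None`` marks criteria not applicable in a cohort: Tanzania had no
#: interventional radiology; Malawi had neither that nor an ICU.
EVENT_COUNTS = MappingProxyType(
    {
        "A0": MappingProxyType({"NL": 1635, "TZ": 66, "MW": 110}),
        "A1": MappingProxyType({"NL": 414, "TZ": 8, "MW": 20}),
        "A2": MappingProxyType({"NL": 242, "TZ": 15, "MW": 69}),
        "A3": MappingProxyType({"NL": 118, "TZ": 30, "MW": 148}),
        "A4": MappingProxyType({"NL": 229, "TZ": 20, "MW": 47}),
        "B0": MappingProxyType({"NL": 1743, "TZ": 184, "MW": 165}),
        "B1": MappingProxyType({"NL": 111, "TZ": None, "MW": None}),
        "B2": MappingProxyType({"NL": 267, "TZ": 59, "MW": 59}),
        "B3": MappingProxyType({"NL": 909, "TZ": 91, "MW": None}),
        "C0": MappingProxyType({"NL": 166, "TZ": 60, "MW": 35}),
        "C1": MappingProxyType({"NL": 115, "TZ": 35, "MW": 13}),
        "C2": MappingProxyType({"NL": 26, "TZ": 4, "MW": 1}),
        "C3": MappingProxyType({"NL": 845, "TZ": 16, "MW": 4}),
        "C4": MappingProxyType({"NL": 27, "TZ": 3, "MW": 11}),
        "C5": MappingProxyType({"NL": 33, "TZ": 33, "MW": 11}),
        "C6": MappingProxyType({"NL": 113, "TZ": 16, "MW": 21}),
    }
)

#: Banded characteristics of the total study population (counts among women
#: with the variable recorded).
AGE_BAND_COUNTS = MappingProxyType(
    {
        "NL": MappingProxyType({"<20": 31, "20-35": 1945, ">35": 536}),
        "TZ": MappingProxyType({"<20": 23, "20-35": 187, ">35": 38}),
        "MW": MappingProxyType({"<20": 83, "20-35": 267, ">35": 34}),
    }
)

PARITY_BAND_COUNTS = MappingProxyType(
    {
        "NL": MappingProxyType({"0": 1258, "1": 867, ">=2": 263}),
        "TZ": MappingProxyType({"0": 52, "1": 30, ">=2": 145}),
        "MW": MappingProxyType({"0": 83, "1": 56, ">=2": 238}),
    }
)

UNITS_BAND_COUNTS = MappingProxyType(
    {
        "NL": MappingProxyType({"0": 734, "1": 6, "2": 88, "3": 50, "4": 802, ">=5": 781}),
        "TZ": MappingProxyType({"0": 64, "1": 108, "2": 54, "3": 12, "4": 8, ">=5": 2}),
        "MW": MappingProxyType({"0": 201, "1": 77, "2": 65, "3": 19, "4": 5, ">=5": 4}),
    }
)

#: "Data available" denominators for the banded characteristics.
DATA_AVAILABLE = MappingProxyType(
    {
        "age": MappingProxyType({"NL": 2512, "TZ": 248, "MW": 384}),
        "parity": MappingProxyType({"NL": 2388, "TZ": 227, "MW": 377}),
        "units_blood": MappingProxyType({"NL": 2461, "TZ": 248, "MW": 371}),
        "mortality": MappingProxyType({"NL": 2538, "TZ": 248, "MW": 386}),
    }
)

#: Locally available critical interventions.
AVAILABLE_INTERVENTIONS = MappingProxyType(
    {
        "NL": frozenset({"interventional_radiology", "laparotomy_non_cs", "icu_admission"}),
        "TZ": frozenset({"laparotomy_non_cs", "icu_admission"}),
        "MW": frozenset({"laparotomy_non_cs"}),
    }
)
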