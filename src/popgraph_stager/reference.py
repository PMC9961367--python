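"""Published ADNI-1 benchmark results for this staging framework.

These are the reported test-set metrics (percent) of the original
access-controlled ADNI-1 evaluation of the CNN+GCN population-graph
pipeline, keyed by edge-assigning function.  They are *reference inputs*,
not outputs of this package: the synthetic experiments reproduce the
qualitative orderings, while the helpers below recompute internally
derivable quantities (F1 from precision/recall, accuracy spreads and gains)
for consistency checking.
"""
from __future__ import annotations

from .metrics import f1_from_pre_rec

#: AD versus CN, demographic edge functions: label -> (ACC, PRE, REC, F1, MCC)
ADCN_RESULTS = {
    "Simg": (86.8, 84.2, 86.5, 85.3, 71.3),
    "Scom(age)": (85.5, 83.8, 83.8, 83.8, 68.2),
    "Scom(gender)": (86.8, 84.2, 86.5, 85.3, 71.3),
    "Scom(apoe4)": (88.0, 82.9, 91.9, 87.2, 74.8),
    "Scom(age,gender)": (86.8, 84.2, 86.5, 85.3, 71.3),
    "Scom(age,apoe4)": (90.4, 89.2, 89.2, 89.2, 78.7),
    "Scom(gender,apoe4)": (89.2, 88.9, 86.5, 87.7, 75.8),
    "Scom(age,gender,apoe4)": (91.6, 91.7, 89.2, 90.4, 81.1),
}

#: AD versus MCI, neuropsychological edge functions:
#: score -> {"Snimg": (...), "Scom": (...)}
ADMCI_RESULTS = {
    "Simg": {"Simg": (66.7, 49.0, 54.0, 51.4, 26.2)},
    "MMSE": {"Snimg": (83.3, 100.0, 48.7, 65.5, 62.3),
             "Scom": (85.1, 95.5, 56.8, 71.2, 65.8)},
    "CDR_SB": {"Snimg": (91.2, 90.9, 81.1, 85.7, 79.6),
               "Scom": (87.7, 89.7, 70.0, 79.1, 71.3)},
    "ADAS11": {"Snimg": (79.0, 78.3, 48.7, 60.0, 49.3),
               "Scom": (79.8, 75.0, 56.8, 64.6, 51.8)},
    "ADAS13": {"Snimg": (80.7, 82.6, 51.4, 63.3, 53.8),
               "Scom": (80.7, 72.7, 64.9, 68.6, 54.9)},
    "FAQ": {"Snimg": (83.3, 75.0, 73.0, 74.0, 61.7),
            "Scom": (85.1, 79.4, 73.0, 76.1, 65.4)},
    "ADNI_MEM": {"Snimg": (78.9, 78.3, 48.7, 60.0, 49.1),
                 "Scom": (79.8, 71.9, 62.2, 66.7, 52.5)},
    "ADNI_EF": {"Snimg": (74.6, 70.0, 37.8, 49.1, 37.1),
                "Scom": (74.6, 72.2, 35.1, 47.3, 36.9)},
    "ADNI_LAN": {"Snimg": (70.2, 60.0, 24.3, 34.6, 23.0),
                 "Scom": (74.6, 64.3, 48.7, 55.4, 38.9)},
    "ADNI_VS": {"Snimg": (67.5, 50.0, 5.0, 9.80, 6.0),
                "Scom": (73.7, 63.0, 46.0, 53.1, 36.3)},
}

#: MCI versus CN, same layout.
MCICN_RESULTS = {
    "Simg": {"Simg": (68.3, 74.4, 75.3, 74.8, 37.7)},
    "MMSE": {"Snimg": (74.8, 73.0, 94.8, 82.5, 56.4),
             "Scom": (78.1, 82.9, 81.8, 82.3, 55.0)},
    "CDR_SB": {"Snimg": (96.8, 95.1, 100.0, 97.5, 93.1),
               "Scom": (96.8, 97.0, 84.4, 90.3, 93.6)},
    "ADAS11": {"Snimg": (77.2, 80.3, 84.4, 82.3, 54.7),
               "Scom": (78.9, 82.3, 84.4, 83.3, 57.3)},
    "ADAS13": {"Snimg": (85.4, 89.3, 87.0, 88.1, 68.9),
               "Scom": (83.7, 84.8, 87.0, 85.9, 66.0)},
    "FAQ": {"Snimg": (82.9, 98.3, 74.0, 84.4, 61.1),
            "Scom": (82.1, 98.3, 72.7, 83.6, 59.2)},
    "ADNI_MEM": {"Snimg": (75.0, 74.0, 94.0, 82.8, 56.2),
                 "Scom": (86.2, 88.5, 89.6, 89.0, 71.0)},
    "ADNI_EF": {"Snimg": (67.5, 66.7, 96.1, 78.7, 48.2),
                "Scom": (67.5, 66.7, 96.1, 78.7, 48.2)},
    "ADNI_LAN": {"Snimg": (69.9, 73.8, 80.5, 77.0, 42.4),
                 "Scom": (69.9, 73.8, 80.5, 77.0, 42.4)},
    "ADNI_VS": {"Snimg": (62.6, 62.6, 100.0, 77.0, 45.5),
                "Scom": (62.6, 62.6, 100.0, 77.0, 45.5)},
}

#: Three-class overall accuracy by edge-assigning function (CDR-SB edges).
THREE_CLASS_ACC = {"Simg": 59.4, "Snimg": 89.4, "Scom": 81.3}

#: Optimal quantitative thresholds beta per task from the benchmark search.
OPTIMAL_BETAS = {
    "ad_mci": {"MMSE": 1.0, "CDR_SB": 2.0, "ADAS11": 3.0, "ADAS13": 3.0,
               "FAQ": 5.0, "ADNI_MEM": 0.3, "ADNI_EF": 0.3, "ADNI_LAN": 0.7,
               "ADNI_VS": 0.5},
    "mci_cn": {"MMSE": 2.0, "CDR_SB": 1.5, "ADAS11": 5.0, "ADAS13": 3.0,
               "FAQ": 1.0, "ADNI_MEM": 1.0, "ADNI_EF": 1.0, "ADNI_LAN": 0.3,
               "ADNI_VS": 0.3},
}

AGE_BETA = 2.0  # optimal age threshold for the AD versus CN demographic graph


def recompute_f1(table_row: tuple[float, ...]) -> float:
    """F1 implied by a benchmark row's precision and recall."""
    _, pre, rec, _, _ = table_row
    return f1_from_pre_rec(pre, rec)


def _flat(results: dict) -> list[tuple[float, ...]]:
    rows = []
    for entry in results.values():
        rows.extend(entry.values())
    return rows


def accuracy_spread(results: dict) -> float:
    """Best-minus-worst accuracy over the non-baseline graph rows."""
    accs = [row[0] for key, entry in results.items() if key != "Simg"
            for row in entry.values()]
    return max(accs) - min(accs)


def recall_gain_over_baseline(results: dict) -> float:
    """Recall of the top-accuracy graph minus the baseline-graph recall."""
    baseline_rec = results["Simg"]["Simg"][2]
    best = max((row for key, entry in results.items() if key != "Simg"
                for row in entry.values()), key=lambda r: r[0])
    return best[2] - baseline_rec


def three_class_gains() -> tuple[float, float]:
    """(min, max) accuracy gain of CDR-SB edges over the baseline graph."""
    base = THREE_CLASS_ACC["Simg"]
    gains = sorted(THREE_CLASS_ACC[k] - base for k in ("Snimg", "Scom"))
    return gains[0], gains[-1]
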