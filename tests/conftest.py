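import numpy as np
import pytest

from apogee import LabeledDataset, VariantRecord
from apogee.features import FeatureMatrix


# Printed evaluation table for the 864-variant corpus: per tool
# (TP, TN, FP, FN, specificity, sensitivity, accuracy, precision, fdr, mcc, mcr).
# Two cells are arithmetically inconsistent with their own row's counts and are
# flagged in the metrics tests (see test_metrics/test_acceptance).
TABLE1 = {
    "PolyPhen2": (120, 369, 263, 100, 0.58, 0.54, 0.57, 0.31, 0.68, 0.11, 42.61),
    "PolyPhen2b": (139, 288, 344, 81, 0.46, 0.63, 0.51, 0.29, 0.71, 0.08, 49.88),
    "SIFT": (31, 560, 81, 191, 0.87, 0.14, 0.68, 0.28, 0.72, 0.02, 31.52),
    "FatHmm": (0, 638, 3, 222, 0.99, 0.00, 0.74, 0.00, 1.00, -0.03, 26.07),
    "FatHmm_W": (82, 473, 168, 141, 0.74, 0.39, 0.64, 0.33, 0.67, 0.11, 35.76),
    "PROVEAN": (128, 329, 312, 94, 0.51, 0.58, 0.53, 0.29, 0.71, 0.08, 47.05),
    "MutationAssessor": (130, 331, 307, 87, 0.52, 0.59, 0.54, 0.29, 0.70, 0.11, 46.08),
    "EFIN_HD": (69, 432, 79, 154, 0.84, 0.31, 0.68, 0.47, 0.53, 0.18, 31.74),
    "EFIN_SP": (83, 511, 130, 140, 0.79, 0.37, 0.69, 0.39, 0.61, 0.17, 31.25),
    "CADD": (69, 495, 146, 154, 0.77, 0.31, 0.65, 0.32, 0.68, 0.08, 34.72),
    "PANTHER": (89, 353, 213, 102, 0.62, 0.47, 0.58, 0.29, 0.71, 0.08, 41.61),
    "PhD-SNP": (141, 291, 350, 82, 0.45, 0.63, 0.51, 0.28, 0.71, 0.07, 50.00),
    "SNAP": (128, 345, 296, 95, 0.54, 0.57, 0.55, 0.30, 0.69, 0.09, 45.25),
    "MetaSNP": (128, 340, 301, 95, 0.53, 0.57, 0.54, 0.29, 0.71, 0.09, 45.83),
    "CAROL": (117, 399, 242, 106, 0.62, 0.52, 0.59, 0.33, 0.67, 0.13, 40.28),
    "Condel": (85, 337, 304, 138, 0.53, 0.38, 0.49, 0.23, 0.78, -0.08, 51.16),
    "COVEC_WMV": (117, 374, 242, 103, 0.61, 0.53, 0.59, 0.33, 0.67, 0.12, 41.27),
    "MToolBox_DS": (142, 276, 365, 81, 0.43, 0.64, 0.48, 0.28, 0.72, 0.06, 51.62),
    "APOGEE_Bootstrap": (162, 564, 61, 77, 0.90, 0.68, 0.84, 0.73, 0.27, 0.59, 15.97),
}

# (tool, statistic) cells whose printed value contradicts the row's own
# TP/TN/FP/FN arithmetic; the value the counts force is given instead.
TABLE1_ERRATA = {
    ("FatHmm_W", "sensitivity"): 82 / 223,   # printed 0.39
    ("Condel", "precision"): 85 / 389,       # printed 0.23, inconsistent with its FDR 0.78
}


@pytest.fixture
def table1():
    return TABLE1


@pytest.fixture
def table1_errata():
    return TABLE1_ERRATA


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_dataset(genes_labels, n_features=2, seed=0):
    """Tiny labeled dataset with random numeric features for structural tests."""
    r = np.random.default_rng(seed)
    records = []
    used = set()
    spans = {"ND5": (12337, 14148), "ND1": (3307, 4262), "CYB": (14747, 15887)}
    for gene, label in genes_labels:
        start, end = spans[gene]
        while True:
            pos = int(r.integers(start, end + 1))
            ref, alt = "A", "G"
            if (pos, alt) not in used:
                used.add((pos, alt))
                break
        records.append(VariantRecord(gene, pos, ref, alt, "M1T", label=label))
    vals = r.normal(size=(len(records), n_features))
    fm = FeatureMatrix(vals, np.zeros_like(vals, bool),
                       [f"f{j}" for j in range(n_features)],
                       ["raw_numeric"] * n_features)
    return LabeledDataset(records, fm)


@pytest.fixture
def tiny_dataset():
    labels = [("ND5", "pathogenic")] * 4 + [("ND1", "neutral")] * 6
    return make_dataset(labels, seed=3)
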