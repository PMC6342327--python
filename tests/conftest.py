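"""Shared fixtures and frozen reference data.

``TABLE1`` is the published table of drugs significantly enriched for
ageing-related targets at the gene level: contingency cells k(l)/m(n),
the conditional-MLE odds ratio to 2 d.p., and the exact-test p and its
BY-adjusted value (family of 1,147 tests) as printed, in scientific
notation with 3 significant figures.  ``TABLE2`` is the published
combined ranking: per-level ranks across the seven levels and their
average to 2 d.p.
"""

from __future__ import annotations

from typing import NamedTuple

import pytest

from gerotarget import SyntheticConfig, generate_study


class Table1Row(NamedTuple):
    drug: str
    k: int
    l: int
    m: int
    n: int
    odds_ratio: float  # printed, 2 d.p.
    p: str  # printed, 3 s.f.
    adj_p: str


TABLE1 = [
    Table1Row("resveratrol", 66, 150, 388, 2221, 2.52, "2.09E-08", "1.82E-04"),
    Table1Row("sunitinib", 18, 12, 436, 2359, 8.11, "4.92E-08", "2.15E-04"),
    Table1Row("genistein", 41, 80, 413, 2291, 2.84, "6.40E-07", "1.86E-03"),
    Table1Row("simvastatin", 39, 77, 415, 2294, 2.80, "1.53E-06", "3.35E-03"),
    Table1Row("tanespimycin", 15, 12, 439, 2359, 6.71, "2.64E-06", "4.62E-03"),
    Table1Row("regorafenib", 12, 7, 442, 2364, 9.16, "4.43E-06", "6.45E-03"),
    Table1Row("egcg", 42, 93, 412, 2278, 2.50, "5.96E-06", "7.44E-03"),
    Table1Row("doxorubicin", 34, 67, 420, 2304, 2.78, "7.20E-06", "7.87E-03"),
    Table1Row("selenium", 14, 12, 440, 2359, 6.25, "9.44E-06", "9.17E-03"),
    Table1Row("celecoxib", 23, 36, 431, 2335, 3.46, "1.58E-05", "1.38E-02"),
    Table1Row("indole-3-carbinol", 13, 11, 441, 2360, 6.32, "1.83E-05", "1.46E-02"),
    Table1Row("hydrogen-peroxide", 59, 165, 395, 2206, 2.00, "2.85E-05", "2.07E-02"),
    Table1Row("gw-501516", 9, 5, 445, 2366, 9.56, "6.23E-05", "3.82E-02"),
    Table1Row("bexarotene", 10, 7, 444, 2364, 7.60, "6.98E-05", "3.82E-02"),
    Table1Row("dorsomorphin", 10, 7, 444, 2364, 7.60, "6.98E-05", "3.82E-02"),
    Table1Row("sorafenib", 23, 41, 431, 2330, 3.03, "7.25E-05", "3.82E-02"),
    Table1Row("sirolimus", 37, 88, 417, 2283, 2.30, "7.42E-05", "3.82E-02"),
    Table1Row("cisplatin", 34, 78, 420, 2293, 2.38, "8.39E-05", "4.07E-02"),
    Table1Row("camp", 36, 86, 418, 2285, 2.29, "1.00E-04", "4.60E-02"),
]

#: total number of drugs tested in the gene-level family TABLE1 heads
TABLE1_M_TESTS = 1147


class Table2Row(NamedTuple):
    drug: str
    ranks: tuple[int, ...]  # gene, ppi, bp, cc, mf, kegg, reactome
    avg: float  # printed, 2 d.p.


TABLE2 = [
    Table2Row("tanespimycin", (5, 26, 57, 43, 44, 39, 9), 31.86),
    Table2Row("imatinib", (63, 3, 21, 34, 12, 66, 38), 33.86),
    Table2Row("sunitinib", (2, 1, 59, 31, 31, 56, 63), 34.71),
    Table2Row("trichostatin", (83, 41, 19, 54, 13, 41, 52), 43.29),
    Table2Row("geldanamycin", (32, 37, 87, 76, 47, 13, 21), 44.71),
    Table2Row("sorafenib", (16, 68, 11, 15, 8, 155, 42), 45.00),
    Table2Row("dasatinib", (41, 12, 43, 81, 62, 49, 35), 46.14),
    Table2Row("erlotinib", (27, 6, 93, 85, 71, 64, 7), 50.43),
    Table2Row("etoposide", (23, 11, 20, 90, 32, 120, 67), 51.86),
    Table2Row("celecoxib", (10, 2, 33, 42, 34, 180, 70), 53.00),
]


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A fast, complete study: all levels present, planted signal strong."""
    return SyntheticConfig(
        n_genes=800,
        n_drugs=150,
        n_ageing_genes=120,
        level_sizes={"go_bp": 120, "go_cc": 40, "go_mf": 40,
                     "kegg": 30, "reactome": 25},
        # strong annotation bias so every level carries enriched terms and
        # the whole seven-level pipeline is exercised
        biased_term_fraction=0.4,
        term_ageing_odds=15.0,
        seed=20190109,
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config):
    """The small study written to disk as a bundle directory."""
    out = tmp_path_factory.mktemp("bundle")
    generate_study(small_config, out)
    return out
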