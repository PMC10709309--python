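"""Gene-program classifiers: threshold rules, exclusivity, and recovery of
planted labels on synthetic expression tables."""

import numpy as np
import pandas as pd
import pytest

from stagekit.expression import (
    ExpressionTable,
    activation_ratio,
    call_differential,
    classify_maternal_genes,
    classify_stage_specific_genes,
    classify_zga_genes,
    stratify_icm_genes,
)
from stagekit.simulate import SyntheticConfig, generate_expression

STAGES = ["FGO", "MII", "1C", "E2C", "L2C", "4C", "8C"]


def table_from_rows(rows: dict[str, list[float]], stages=STAGES) -> ExpressionTable:
    return ExpressionTable(
        pd.DataFrame.from_dict(rows, orient="index", columns=[f"{s}:1" for s in stages])
    )


class TestZgaRules:
    @pytest.mark.parametrize(
        "fpkm,expected",
        [
            # FGO, MII, 1C, E2C, L2C, 4C, 8C
            ([0.5, 1.0, 0.5, 6.0, 8.0, 8, 8], "minor_ZGA"),     # 6 > 5, 3x over 1.0
            ([0.5, 1.0, 0.5, 2.0, 8.0, 8, 8], "major_ZGA"),     # first met at L2C
            ([6.0, 7.0, 7.0, 7.0, 40.0, 30, 30],
             "major_ZGA_oocyte_upregulated"),                    # 40/7 ~ 5.7 >= 5
            ([0.0, 0.0, 0.0, 4.9, 4.9, 4, 4], "none"),          # never exceeds 5
            ([0.5, 1.0, 0.5, 6.0, 2.0, 2, 2], "minor_ZGA"),
            ([2.0, 2.0, 2.0, 5.5, 5.5, 5, 5], "none"),          # 5.5 < 3 x 2.0
        ],
    )
    def test_rule_application(self, fpkm, expected):
        (call,) = classify_zga_genes(table_from_rows({"g": fpkm}))
        assert call.program == expected

    def test_silent_oocyte_uses_pseudocount_floor(self):
        # oocyte FPKM 0: fold change measured against the 0.1 floor
        (call,) = classify_zga_genes(table_from_rows({"g": [0, 0, 0, 5.1, 6, 6, 6]}))
        assert call.program == "minor_ZGA"


class TestMaternalRule:
    @pytest.mark.parametrize(
        "fgo,l2c,expected",
        [
            (30, 9, "maternal"),   # 9 <= 30/3
            (30, 11, "none"),      # 11 > 10
            (4, 1, "none"),        # not oocyte-expressed
            (30, 10, "maternal"),  # boundary: exactly 3-fold down
        ],
    )
    def test_rule_application(self, fgo, l2c, expected):
        (call,) = classify_maternal_genes(
            table_from_rows({"g": [fgo, 0.2, 5, 5, l2c, 1, 1]})
        )
        assert call.program == expected


class TestStageSpecificRule:
    @pytest.mark.parametrize(
        "fpkm,expected",
        [
            ([0.2, 0.4, 0.3, 0.5, 0.6, 7, 9], "stage_specific:4C"),
            ([0.2, 0.4, 0.3, 0.5, 2.0, 7, 9], "none"),  # L2C not < 1
            ([0.2, 0.4, 0.3, 0.5, 0.6, 2, 3], "none"),  # never > 5
            ([0.2, 0.4, 0.3, 6.0, 9.0, 9, 9], "stage_specific:E2C"),
            ([6.0, 0.4, 0.3, 0.5, 0.6, 7, 9], "none"),  # expressed at FGO itself
        ],
    )
    def test_earliest_qualifying_stage(self, fpkm, expected):
        (call,) = classify_stage_specific_genes(table_from_rows({"g": fpkm}), STAGES)
        assert call.program == expected


class TestIcmStratification:
    @pytest.mark.parametrize("fpkm_8c,side", [(1.2, "early_ICM"), (0.5, "late_ICM"),
                                              (1.0, "early_ICM")])
    def test_threshold(self, fpkm_8c, side):
        table = table_from_rows({"g": [0, 0, 0, 0, 0, 0, fpkm_8c]})
        parts = stratify_icm_genes(["g"], table)
        assert "g" in parts[side]

    def test_partitions_input(self):
        rng = np.random.default_rng(1)
        rows = {f"g{i}": [0] * 6 + [float(v)] for i, v in enumerate(rng.uniform(0, 3, 40))}
        parts = stratify_icm_genes(list(rows), table_from_rows(rows))
        assert parts["early_ICM"] | parts["late_ICM"] == set(rows)
        assert not parts["early_ICM"] & parts["late_ICM"]


def test_programs_mutually_exclusive_on_random_tables():
    """No gene can be minor ZGA, major ZGA and/or maternal at once: the
    threshold windows are disjoint by construction."""
    rng = np.random.default_rng(2)
    rows = {f"g{i}": list(rng.uniform(0, 60, len(STAGES))) for i in range(300)}
    table = table_from_rows(rows)
    zga = {c.gene_id: c.program for c in classify_zga_genes(table)}
    mat = {c.gene_id: c.program for c in classify_maternal_genes(table)}
    for g in rows:
        labels = [p for p in (zga[g], mat[g]) if p != "none"]
        assert len(labels) <= 1, f"{g} got {labels}"


class TestCallDifferential:
    def test_log2fc_arithmetic_and_up_call(self):
        ctrl = pd.DataFrame({"r1": [10.0]}, index=["g"])
        kd = pd.DataFrame({"r1": [60.0]}, index=["g"])
        (res,) = call_differential(ctrl, kd, pvalues={"g": 1e-4})
        assert res.log2_fold_change == pytest.approx(np.log2(60.01 / 10.01), abs=1e-9)
        assert res.call == "up"

    def test_magnitude_below_two_is_ns(self):
        ctrl = pd.DataFrame({"r1": [10.0]}, index=["g"])
        kd = pd.DataFrame({"r1": [37.0]}, index=["g"])  # log2FC ~ 1.9
        (res,) = call_differential(ctrl, kd, pvalues={"g": 1e-4})
        assert res.call == "ns"

    def test_unit_pvalues_silence_everything(self):
        rng = np.random.default_rng(3)
        idx = [f"g{i}" for i in range(50)]
        ctrl = pd.DataFrame(rng.uniform(1, 100, (50, 2)), index=idx)
        kd = pd.DataFrame(rng.uniform(1, 100, (50, 2)), index=idx)
        res = call_differential(ctrl, kd, pvalues={g: 1.0 for g in idx})
        assert all(r.call == "ns" for r in res)

    def test_matches_exhaustive_threshold_oracle(self):
        """With p-values supplied, calls equal a direct sweep of the two
        thresholds applied gene by gene (after BH adjustment)."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        idx = [f"g{i}" for i in range(200)]
        ctrl = pd.DataFrame(rng.uniform(0, 50, (200, 3)), index=idx)
        kd = pd.DataFrame(rng.uniform(0, 50, (200, 3)), index=idx)
        pvals = pd.Series(rng.uniform(0, 0.05, 200), index=idx)
        res = call_differential(ctrl, kd, pvalues=pvals)
        fdr = pd.Series(multipletests(pvals, method="fdr_bh")[1], index=idx)
        for r in res:
            fc = np.log2((kd.loc[r.gene_id].mean() + 0.01)
                         / (ctrl.loc[r.gene_id].mean() + 0.01))
            if fdr[r.gene_id] < 0.01 and abs(fc) >= 2:
                assert r.call == ("up" if fc > 0 else "down")
            else:
                assert r.call == "ns"

    def test_empty_table_raises(self):
        empty = pd.DataFrame(columns=["r1"])
        with pytest.raises(ValueError, match="no genes"):
            call_differential(empty, empty)


class TestActivationRatio:
    def test_pseudocounted_ratio(self):
        table = table_from_rows({"g": [0, 0, 1.0, 0, 10.0, 0, 0]})
        ratios, summary = activation_ratio(table, "L2C", "1C", ["g"])
        assert ratios["g"] == pytest.approx(10.01 / 1.01)
        assert summary["median"] == pytest.approx(10.01 / 1.01)

    def test_identical_stages_give_one(self):
        table = table_from_rows({"g": [0, 0, 5.0, 0, 5.0, 0, 0]})
        ratios, _ = activation_ratio(table, "L2C", "1C", ["g"])
        assert ratios["g"] == pytest.approx(1.0)

    def test_empty_gene_set(self):
        table = table_from_rows({"g": [0] * 7})
        ratios, summary = activation_ratio(table, "L2C", "1C", [])
        assert ratios.empty and summary == {}


def test_classifiers_recover_planted_labels():
    """On the synthetic cohort (n=500 genes, 0.2 log-unit replicate noise)
    each classifier recovers >= 90% of its planted labels."""
    table, truth = generate_expression(SyntheticConfig(seed=5))
    zga = {c.gene_id: c.program for c in classify_zga_genes(table)}
    mat = {c.gene_id: c.program for c in classify_maternal_genes(table)}
    stg = {c.gene_id: c.program for c in classify_stage_specific_genes(
        table, ["FGO", "MII", "1C", "E2C", "L2C", "4C", "8C"])}
    for calls, prefixes in (
        (zga, ("minor_ZGA", "major_ZGA")),
        (mat, ("maternal",)),
        (stg, ("stage_specific",)),
    ):
        planted = {g: p for g, p in truth.gene_programs.items()
                   if p.startswith(prefixes)}
        hit = sum(calls[g] == p for g, p in planted.items())
        assert hit / len(planted) >= 0.9, prefixes
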