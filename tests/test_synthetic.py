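import numpy as np
import pandas as pd
import pytest

from citepipe import synthetic
from citepipe.synthetic import (
    PlantedDE,
    PlantedShift,
    default_config,
    generate_cohort,
    truth_report,
)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        cfg = default_config(seed=0, n_participants_per_group=1, cells_per_participant=10)
        cfg.cell_type_fractions["HIV-"]["B"] += 0.5
        with pytest.raises(ValueError, match="cell_type_fractions"):
            cfg.validate()

    def test_doublet_rate_bounds(self):
        cfg = default_config(seed=0, n_participants_per_group=1, cells_per_participant=10)
        cfg.doublet_rate = 0.6
        with pytest.raises(ValueError, match="doublet_rate"):
            cfg.validate()

    def test_negative_sd_rejected(self):
        cfg = default_config(seed=0, n_participants_per_group=1, cells_per_participant=10)
        cfg.adt_background["CD3"] = (1.0, -0.5)
        with pytest.raises(ValueError, match="adt_background"):
            cfg.validate()

    def test_zero_rna_rate_rejected(self):
        cfg = default_config(seed=0, n_participants_per_group=1, cells_per_participant=10)
        cfg.rna_rates["B"]["GENE001"] = 0.0
        with pytest.raises(ValueError, match="rna_rates"):
            cfg.validate()


class TestConfigSerialization:
    def test_roundtrip_generates_identical_cohort(self):
        from citepipe.synthetic import SyntheticConfig

        cfg = default_config(
            seed=4, n_participants_per_group=1, cells_per_participant=40,
            planted_de=[PlantedDE("GENE001", "B", "HIV-", 1.0)],
            planted_prop_shift=[PlantedShift("NK", "HIV-", 1.5)],
        )
        back = SyntheticConfig.from_dict(cfg.to_dict())
        adt1, *_ = generate_cohort(cfg)
        adt2, *_ = generate_cohort(back)
        assert np.array_equal(adt1.counts, adt2.counts)

    def test_dict_is_yaml_serializable(self, tmp_path):
        import yaml

        cfg = default_config(seed=0, n_participants_per_group=1, cells_per_participant=10)
        text = yaml.safe_dump(cfg.to_dict())
        assert yaml.safe_load(text)["cells_per_participant"] == 10


class TestGenerateCohort:
    def test_zero_doublet_rate_means_no_doublets(self):
        cfg = default_config(seed=0, n_participants_per_group=1,
                             cells_per_participant=50, doublet_rate=0.0)
        *_, truth = generate_cohort(cfg)
        assert not truth.cells["is_doublet"].any()

    def test_same_seed_bit_identical(self):
        cfg = default_config(seed=5, n_participants_per_group=1, cells_per_participant=60)
        adt1, rna1, tags1, cells1, _ = generate_cohort(cfg)
        adt2, rna2, tags2, cells2, _ = generate_cohort(cfg)
        assert np.array_equal(adt1.counts, adt2.counts)
        assert np.array_equal(rna1.counts, rna2.counts)
        assert np.array_equal(tags1.counts, tags2.counts)
        pd.testing.assert_frame_equal(cells1, cells2)

    def test_different_seed_differs(self):
        cfg1 = default_config(seed=5, n_participants_per_group=1, cells_per_participant=60)
        cfg2 = default_config(seed=6, n_participants_per_group=1, cells_per_participant=60)
        adt1, *_ = generate_cohort(cfg1)
        adt2, *_ = generate_cohort(cfg2)
        assert not np.array_equal(adt1.counts, adt2.counts)

    def test_full_scale_doublet_count_within_3sd(self):
        # 4 groups x 8 participants x 1300 cells = 41,600 cells; doublet count
        # is Binomial(41600, 0.075): check within 3 binomial SDs.
        cfg = default_config(seed=1)
        adt, rna, tags, cells, truth = generate_cohort(cfg)
        n = adt.n_cells
        assert n == 41_600
        expected = 0.075 * n
        sd = np.sqrt(n * 0.075 * 0.925)
        observed = int(truth.cells["is_doublet"].sum())
        assert abs(observed - expected) <= 3 * sd

    def test_every_cell_appears_exactly_once(self, small_cohort):
        adt, rna, tags, cells, truth = small_cohort
        assert adt.cells.is_unique
        assert adt.cells.equals(rna.cells)
        assert adt.cells.equals(tags.cells)
        assert adt.cells.equals(cells.index)
        assert adt.cells.equals(truth.cells.index)

    def test_doublet_partner_same_plate_tagging(self, small_cohort):
        adt, rna, tags, cells, truth = small_cohort
        dbl = truth.cells[truth.cells["is_doublet"]]
        assert (dbl["partner_type"] != "").all()


class TestInvariants:
    def test_positive_markers_bimodal_by_bic(self, small_cohort):
        # two-component BIC beats one-component BIC for every marker with both
        # positive and negative populations, at n >= 2000 cells
        from citepipe.qc import clr_normalize
        from citepipe.thresholding import fit_mixture_1d, mixture_loglik

        adt, *_, truth = small_cohort
        clr = clr_normalize(adt)
        assert len(clr) >= 2000
        types_with = truth.positive_markers
        all_types = set(types_with)
        for marker in clr.columns:
            pos_types = {t for t in all_types if marker in types_with[t]}
            if not pos_types or pos_types == all_types:
                continue  # no mixed population for this marker
            x = clr[marker].to_numpy()
            fit = fit_mixture_1d(x, seed=0)
            assert fit.converged, marker
            bic2 = -2 * fit.loglik + 5 * np.log(len(x))
            ll1 = mixture_loglik(
                x, np.array([1.0 - 1e-12, 1e-12]),
                np.array([x.mean(), x.mean()]),
                np.array([x.std(), x.std()]),
            )
            bic1 = -2 * ll1 + 2 * np.log(len(x))
            assert bic2 < bic1, marker

    def test_singlet_tag_dominance(self, small_cohort):
        adt, rna, tags, cells, truth = small_cohort
        singlet = ~truth.cells["is_doublet"].to_numpy()
        counts = tags.counts[singlet].astype(float)
        part = np.sort(counts, axis=1)
        top, second = part[:, -1], part[:, -2]
        ratio = np.where(second == 0, np.inf, top / np.maximum(second, 1e-12))
        assert (ratio >= 5).mean() >= 0.99


class TestTruthReport:
    def test_empty_planted_de_gives_empty_de_section(self, small_cohort):
        *_, truth = small_cohort
        report = truth_report(truth)
        assert (report["kind"] == "de").sum() == 0

    def test_three_planted_de_genes_three_rows(self):
        cfg = default_config(
            seed=0, n_participants_per_group=1, cells_per_participant=20,
            planted_de=[
                PlantedDE("GENE001", "B", "HIV-", 2.0),
                PlantedDE("GENE002", "NK", "HIV+CVD-", -1.0),
                PlantedDE("GENE003", "CM", "HIV+CVD+", 1.5),
            ],
        )
        *_, truth = generate_cohort(cfg)
        report = truth_report(truth)
        assert (report["kind"] == "de").sum() == 3

    def test_prop_shift_multiplier_echoed(self):
        cfg = default_config(
            seed=0, n_participants_per_group=1, cells_per_participant=20,
            planted_prop_shift=[PlantedShift("NK", "HIV+CVD+", 2.0)],
        )
        *_, truth = generate_cohort(cfg)
        report = truth_report(truth)
        row = report[report["kind"] == "prop_shift"].iloc[0]
        assert row["multiplier"] == 2.0
        assert row["cell_type"] == "NK"
        assert row["group"] == "HIV+CVD+"

    def test_planted_de_changes_expression(self):
        planted = PlantedDE("GENE001", "CD4 T", "HIV+CVD+", 2.0)
        cfg = default_config(seed=2, n_participants_per_group=2,
                             cells_per_participant=300, planted_de=[planted])
        adt, rna, tags, cells, truth = generate_cohort(cfg)
        frame = rna.to_frame().join(cells).join(truth.cells)
        sub = frame[(frame["true_type"] == "CD4 T") & ~frame["is_doublet"]]
        hit = sub[sub["group"] == "HIV+CVD+"]["GENE001"].mean()
        rest = sub[sub["group"] != "HIV+CVD+"]["GENE001"].mean()
        assert hit / rest == pytest.approx(4.0, rel=0.25)

    def test_planted_shift_changes_fraction(self):
        cfg = default_config(
            seed=2, n_participants_per_group=2, cells_per_participant=500,
            planted_prop_shift=[PlantedShift("NK", "HIV+CVD+", 2.0)],
        )
        adt, rna, tags, cells, truth = generate_cohort(cfg)
        frame = cells.join(truth.cells)
        sing = frame[~frame["is_doublet"]]
        f_hit = (sing[sing["group"] == "HIV+CVD+"]["true_type"] == "NK").mean()
        f_rest = (sing[sing["group"] == "HIV-"]["true_type"] == "NK").mean()
        assert f_hit > 1.3 * f_rest
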