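"""Synthetic matrix database: generator, inclusion filters, exchange format."""

import numpy as np
import pytest

from transientmpm import (
    GeneratorConfig,
    PopulationModel,
    apply_inclusion_filters,
    dominant_eigenvalue,
    generate_database,
    generate_matrix_set,
    is_ergodic,
    read_matrix_csv,
    write_matrix_csv,
)
from transientmpm.exceptions import FormatError, ValidationError


def survival_column_sums(A):
    """Column sums of the survival part (everything except the top-row
    fecundities added on top of any stasis there)."""
    S = A.copy()
    return S.sum(axis=0)


class TestGenerateMatrixSet:
    def test_zero_cv_identical(self):
        mats = generate_matrix_set(4, 5, "shrub", temporal_cv=0.0, seed=1)
        assert len(mats) == 5
        for A in mats[1:]:
            np.testing.assert_array_equal(A, mats[0])

    def test_target_lambda_reached(self):
        for target in (-0.2, 0.0, 0.15):
            A = generate_matrix_set(3, 1, "herbaceous_perennial",
                                    temporal_cv=0.0, target_log_lambda=target, seed=2)[0]
            assert np.log(dominant_eigenvalue(A)) == pytest.approx(target, abs=1e-6)

    def test_survival_bound_respected(self, rng):
        """Every column's survival-entry sum stays <= 1.  Fecundities live
        in the top row of the last ceil(dim/2) ("reproductive") columns and
        are excluded from the sum."""
        import math

        for trial in range(20):
            form = ["tree", "palm", "succulent", "shrub", "herbaceous_perennial"][trial % 5]
            dim = int(rng.integers(2, 10))
            n_repro = max(1, math.ceil(dim / 2))
            mats = generate_matrix_set(dim, 4, form, temporal_cv=0.4, seed=trial)
            for A in mats:
                surv = A.sum(axis=0).copy()
                surv[dim - n_repro :] -= A[0, dim - n_repro :]
                assert np.all(surv <= 1.0 + 1e-12)

    def test_matrices_ergodic(self, rng):
        """>= 99% of generated matrices are irreducible and primitive."""
        n_total = n_ok = 0
        for trial in range(100):
            dim = int(rng.integers(2, 10))
            form = ["tree", "herbaceous_perennial"][trial % 2]
            for A in generate_matrix_set(dim, 10, form, temporal_cv=0.3, seed=1000 + trial):
                n_total += 1
                n_ok += bool(is_ergodic(A))
        assert n_total == 1000
        assert n_ok / n_total >= 0.99

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            generate_matrix_set(1, 3, "tree")
        with pytest.raises(ValidationError):
            generate_matrix_set(3, 0, "tree")
        with pytest.raises(ValidationError):
            generate_matrix_set(3, 3, "lichen")


class TestGenerateDatabase:
    def test_bookkeeping_counts(self):
        cfg = GeneratorConfig(n_species=10, populations_per_species=2, seed=5)
        db = generate_database(cfg)
        assert len(db) == 20
        assert db.bookkeeping["species_id"].nunique() == 10
        forms = {p.growth_form for p in db}
        assert forms <= {"herbaceous_perennial", "shrub", "succulent", "palm", "tree"}

    def test_seed_reproducibility(self):
        cfg = GeneratorConfig(n_species=6, populations_per_species=2, seed=9)
        db1, db2 = generate_database(cfg), generate_database(cfg)
        assert [p.population_id for p in db1] == [p.population_id for p in db2]
        for p1, p2 in zip(db1, db2):
            for A1, A2 in zip(p1.matrices, p2.matrices):
                np.testing.assert_array_equal(A1, A2)

    def test_dimension_effect_couples_cv(self):
        cfg = GeneratorConfig(n_species=60, dimension_effect=0.2, seed=12)
        db = generate_database(cfg)
        bk = db.bookkeeping
        r = np.corrcoef(bk["matrix_dimension"], np.log(bk["realized_cv"]))[0, 1]
        assert r > 0.3

    def test_log_lambda_centered(self):
        """log lambda_max across all matrices of a default database is
        distributed around zero (mean within 0.05)."""
        db = generate_database(GeneratorConfig(n_species=50, seed=21))
        lams = [np.log(dominant_eigenvalue(A)) for p in db for A in p.matrices]
        assert abs(np.mean(lams)) < 0.05

    def test_species_share_form_and_dimension(self):
        db = generate_database(GeneratorConfig(n_species=8, populations_per_species=3, seed=2))
        for sid, grp in db.bookkeeping.groupby("species_id"):
            assert grp["growth_form"].nunique() == 1
            assert grp["matrix_dimension"].nunique() == 1


class TestInclusionFilters:
    def pops(self):
        A = np.array([[0.1, 2.0], [0.5, 0.1]])
        mk = lambda i, **kw: PopulationModel(f"p{i}", f"s{i}", "tree", [A] * kw.pop("n", 3), **kw)
        return [
            mk(0),
            mk(1, n=2),
            mk(2, manipulated=True),
            mk(3, is_mean_matrix=True),
            mk(4),
        ]

    def test_filters_and_log(self):
        kept, log = apply_inclusion_filters(self.pops())
        assert [p.population_id for p in kept] == ["p0", "p4"]
        reasons = dict(log)
        assert reasons["p1"] == "fewer than 3 matrices"
        assert "manipulated" in reasons["p2"]
        assert "mean" in reasons["p3"]

    def test_identity_on_compliant_set(self):
        pops = [p for p in self.pops() if p.population_id in ("p0", "p4")]
        kept, log = apply_inclusion_filters(pops)
        assert len(kept) == 2 and log == []

    def test_explicit_species_exclusion(self):
        kept, log = apply_inclusion_filters(self.pops(), exclude_species={"s0"})
        assert [p.population_id for p in kept] == ["p4"]


class TestExchangeFormat:
    def test_round_trip_identity(self, tmp_path):
        cfg = GeneratorConfig(n_species=10, populations_per_species=2, seed=31)
        db = generate_database(cfg)
        path = tmp_path / "db.csv"
        write_matrix_csv(db, path)
        back = read_matrix_csv(path)
        assert len(back) == len(db)
        for p1, p2 in zip(db, back):
            assert p1.population_id == p2.population_id
            assert p1.species_id == p2.species_id
            assert p1.growth_form == p2.growth_form
            assert (p1.manipulated, p1.is_mean_matrix) == (p2.manipulated, p2.is_mean_matrix)
            for A1, A2 in zip(p1.matrices, p2.matrices):
                np.testing.assert_array_equal(A1, A2)

    def test_density_contract(self, tmp_path):
        A = np.array([[0.1, 2.0], [0.5, 0.1]])
        pop = PopulationModel("p0", "s0", "tree", [A])
        path = tmp_path / "one.csv"
        write_matrix_csv([pop], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + 4  # header + 4 dense cells of a 2x2 matrix

    def test_negative_value_cites_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_matrix_csv(
            [PopulationModel("p0", "s0", "tree", [np.array([[0.1, 2.0], [0.5, 0.1]])])], path
        )
        text = path.read_text().splitlines()
        text[2] = text[2].replace("2.0", "-2.0")
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(FormatError, match="line 3"):
            read_matrix_csv(path)

    def test_duplicate_cell_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        write_matrix_csv(
            [PopulationModel("p0", "s0", "tree", [np.array([[0.1, 2.0], [0.5, 0.1]])])], path
        )
        lines = path.read_text().splitlines()
        lines.append(lines[-1])  # repeat the last cell
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_matrix_csv(path)

    def test_ragged_matrix_rejected(self, tmp_path):
        path = tmp_path / "ragged.csv"
        write_matrix_csv(
            [PopulationModel("p0", "s0", "tree", [np.array([[0.1, 2.0], [0.5, 0.1]])])], path
        )
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop one cell
        with pytest.raises(FormatError, match="ragged"):
            read_matrix_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("population_id,row,col,value\np0,1,1,0.5\n")
        with pytest.raises(ValidationError, match="missing"):
            read_matrix_csv(path)
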