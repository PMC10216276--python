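"""CSV round-trips, validation, and the planted-signal fixture generator."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from qdinn.data_io import (
    SMILES_POOL,
    generate_fixtures,
    load_bundle,
    pair_count,
    write_bundle,
)


def test_smiles_pool_all_valid():
    assert len(SMILES_POOL) >= 50
    for smiles in SMILES_POOL:
        mol = Chem.MolFromSmiles(smiles)
        assert mol is not None and mol.GetNumAtoms() >= 1, smiles


@pytest.mark.parametrize(
    "n_drugs,n_cells,expected", [(1, 1, 1), (10, 7, 70), (223, 948, 211404)]
)
def test_pair_count(n_drugs, n_cells, expected):
    assert pair_count(n_drugs, n_cells) == expected


def test_pair_count_rejects_nonpositive():
    with pytest.raises(ValueError):
        pair_count(0, 5)


class TestGenerateFixtures:
    def test_cross_product_and_positivity(self):
        bundle = generate_fixtures(5, 10, seed=7)
        assert len(bundle.responses) == 50
        assert len(bundle.drugs) == 5 and len(bundle.cells) == 10
        assert all(r.ic50_raw > 0 for r in bundle.responses)
        bundle.validate()

    def test_same_seed_reproduces_bundle(self):
        a = generate_fixtures(4, 6, seed=11, noise_sd=0.2)
        b = generate_fixtures(4, 6, seed=11, noise_sd=0.2)
        assert a.drugs == b.drugs
        for cid in a.cells:
            np.testing.assert_array_equal(a.cells[cid].mutations, b.cells[cid].mutations)
        assert [(r.drug_id, r.cell_id, r.ic50_raw) for r in a.responses] == [
            (r.drug_id, r.cell_id, r.ic50_raw) for r in b.responses
        ]

    def test_noise_free_matches_planted_formula(self):
        """Independent recomputation of log(ic50) = 1.5 z_cell + z_drug."""
        bundle = generate_fixtures(6, 9, seed=3, noise_sd=0.0)
        heavy = np.array(
            [
                Chem.MolFromSmiles(s).GetNumHeavyAtoms()
                for s in bundle.drugs.values()
            ],
            dtype=float,
        )
        z_drug = (heavy - heavy.mean()) / heavy.std()
        counts = np.array(
            [p.mutations[:20].sum() for p in bundle.cells.values()]
        )
        z_cell = (counts - counts.mean()) / counts.std()
        drug_ids = list(bundle.drugs)
        cell_ids = list(bundle.cells)
        for rec in bundle.responses:
            expected = np.exp(
                1.5 * z_cell[cell_ids.index(rec.cell_id)]
                + 1.0 * z_drug[drug_ids.index(rec.drug_id)]
            )
            assert rec.ic50_raw == pytest.approx(expected, rel=1e-12)

    def test_pool_exhaustion_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            generate_fixtures(len(SMILES_POOL) + 1, 2, seed=0)


def test_write_load_round_trip(tmp_path):
    bundle = generate_fixtures(4, 5, seed=2, noise_sd=0.3)
    paths = write_bundle(bundle, tmp_path)
    loaded = load_bundle(paths["drugs"], paths["cells"], paths["responses"])
    assert loaded.drugs == bundle.drugs
    for cid in bundle.cells:
        np.testing.assert_array_equal(
            loaded.cells[cid].mutations, bundle.cells[cid].mutations
        )
    assert [(r.drug_id, r.cell_id) for r in loaded.responses] == [
        (r.drug_id, r.cell_id) for r in bundle.responses
    ]
    for got, want in zip(loaded.responses, bundle.responses):
        assert got.ic50_raw == want.ic50_raw  # exact, not approximate
        assert got.ic50_norm == want.ic50_norm


class TestLoadValidation:
    @pytest.fixture
    def paths(self, tmp_path):
        return write_bundle(generate_fixtures(3, 4, seed=1), tmp_path)

    def test_unknown_drug_named_with_row(self, tmp_path, paths):
        df = pd.read_csv(paths["responses"])
        df.loc[5, "drug_id"] = "GHOST"
        df.to_csv(paths["responses"], index=False)
        with pytest.raises(ValueError, match=r"row 5.*GHOST"):
            load_bundle(paths["drugs"], paths["cells"], paths["responses"])

    def test_nonpositive_ic50_rejected(self, paths):
        df = pd.read_csv(paths["responses"])
        df.loc[2, "ic50"] = 0.0
        df.to_csv(paths["responses"], index=False)
        with pytest.raises(ValueError, match=r"row 2.*> 0"):
            load_bundle(paths["drugs"], paths["cells"], paths["responses"])

    def test_missing_column_named(self, paths):
        df = pd.read_csv(paths["drugs"]).rename(columns={"smiles": "structure"})
        df.to_csv(paths["drugs"], index=False)
        with pytest.raises(ValueError, match="smiles"):
            load_bundle(paths["drugs"], paths["cells"], paths["responses"])

    def test_wrong_mutation_width_rejected(self, paths):
        df = pd.read_csv(paths["cells"])
        df = df.drop(columns=[df.columns[-1]])
        df.to_csv(paths["cells"], index=False)
        with pytest.raises(ValueError, match="735"):
            load_bundle(paths["drugs"], paths["cells"], paths["responses"])

    def test_schema_mapping_adapts_foreign_headers(self, paths):
        """GDSC-style exports with vendor column names load via the schema."""
        for name, renames in (
            ("drugs", {"drug_id": "DRUG_ID", "smiles": "canonical_smiles"}),
            ("responses", {"drug_id": "DRUG_ID", "cell_id": "COSMIC_ID",
                           "ic50": "IC50_RESULT"}),
            ("cells", {"cell_id": "COSMIC_ID"}),
        ):
            df = pd.read_csv(paths[name]).rename(columns=renames)
            df.to_csv(paths[name], index=False)
        bundle = load_bundle(
            paths["drugs"], paths["cells"], paths["responses"],
            schema={"drug_id": "DRUG_ID", "smiles": "canonical_smiles",
                    "cell_id": "COSMIC_ID", "ic50": "IC50_RESULT"},
        )
        assert len(bundle.responses) == 12


def test_noise_free_fixtures_are_learnable_below_target_variance():
    """With the planted signal and no noise, a trained hybrid model beats
    the trivial predict-the-mean baseline: its test MSE falls below the
    variance of the normalized targets. (Several minutes of training.)"""
    from qdinn.model import DrugResponseModel
    from qdinn.pipeline import PreparedData, TrainConfig, split_dataset, train

    bundle = generate_fixtures(6, 40, seed=5, noise_sd=0.0)
    config = TrainConfig(n_train=None, n_test=None, epochs=80, seed=5)
    train_records, test_records = split_dataset(bundle.responses, config)
    model = DrugResponseModel("hybrid", seed=config.effective_init_seed)
    run = train(model, train_records, test_records, PreparedData(bundle), config)
    target_variance = float(
        np.var([r.ic50_norm for r in bundle.responses])
    )
    assert run.final_test_mse < target_variance


def test_full_cross_product_toy_tables(tmp_path):
    """3 drugs x 4 cells with every pair present -> 12 validated responses."""
    bundle = generate_fixtures(3, 4, seed=0)
    paths = write_bundle(bundle, tmp_path)
    loaded = load_bundle(paths["drugs"], paths["cells"], paths["responses"])
    assert len(loaded.responses) == pair_count(3, 4) == 12
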