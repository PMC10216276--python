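"""Dataset loading, validation, and seeded synthetic fixtures.

Three CSV tables describe a drug-sensitivity screen (GDSC-style):

* ``drugs.csv`` — ``drug_id,smiles``;
* ``cells.csv`` — ``cell_id`` followed by 735 columns of 0/1 mutation
  indicators (column names are free; order defines the feature order);
* ``responses.csv`` — ``drug_id,cell_id,ic50`` with strictly positive raw
  IC50 values (taken on whatever dose scale the source provides).

All files are UTF-8, comma-separated, ``.`` decimal, header row mandatory.
Real exports rarely use these exact column names, so ``load_bundle`` accepts
a column-mapping schema (e.g. ``{"drug_id": "DRUG_ID", "smiles":
"canonical_smiles", ...}``) instead of hard-coding any vendor's headers.

The synthetic generator makes the package testable without downloads. It
draws real small-molecule SMILES from a curated pool, samples sparse binary
mutation profiles, and plants a signal-plus-noise response

    log(ic50) = 1.5 * z_cell + 1.0 * z_drug + eps,   eps ~ N(0, noise_sd^2)

where ``z_cell`` is the standardized count of ones among the first 20
mutation slots and ``z_drug`` the standardized heavy-atom count — so both
branches of the model carry real, recoverable signal. Responses cover the
full drug x cell cross product. Generation is a pure function of its
arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoders import CELL_PROFILE_DIM, CellLineProfile
from .model import ResponseRecord, normalize_ic50

__all__ = [
    "SMILES_POOL",
    "DatasetBundle",
    "load_bundle",
    "write_bundle",
    "generate_fixtures",
    "pair_count",
]

#: Curated pool of valid small-molecule SMILES (common drugs, metabolites and
#: simple organics) used by the fixture generator.
SMILES_POOL: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",       # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "c1ccccc1",                         # benzene
    "Cc1ccccc1",                        # toluene
    "Oc1ccccc1",                        # phenol
    "CCO",                              # ethanol
    "CC(=O)O",                          # acetic acid
    "C1CCCCC1",                         # cyclohexane
    "c1ccc2ccccc2c1",                   # naphthalene
    "c1ccncc1",                         # pyridine
    "c1ccc2[nH]ccc2c1",                 # indole
    "C(C(=O)O)N",                       # glycine
    "CC(N)C(=O)O",                      # alanine
    "NC(CO)C(=O)O",                     # serine
    "OC(=O)CCC(=O)O",                   # succinic acid
    "OC(=O)C=CC(=O)O",                  # fumaric acid
    "OCC(O)CO",                         # glycerol
    "CC(O)C(=O)O",                      # lactic acid
    "Nc1ccccc1",                        # aniline
    "O=C(O)c1ccccc1",                   # benzoic acid
    "COc1ccccc1",                       # anisole
    "CC(C)O",                           # isopropanol
    "CCCCO",                            # butanol
    "O=C1CCCCC1",                       # cyclohexanone
    "c1ccsc1",                          # thiophene
    "c1ccoc1",                          # furan
    "c1cc[nH]c1",                       # pyrrole
    "c1cnc2[nH]cnc2n1",                 # purine
    "Cn1ccnc1",                         # 1-methylimidazole
    "OCC1OC(O)C(O)C(O)C1O",             # glucose (open ring form)
    "CSCCC(N)C(=O)O",                   # methionine
    "NC(Cc1ccccc1)C(=O)O",              # phenylalanine
    "NC(Cc1ccc(O)cc1)C(=O)O",           # tyrosine
    "NC(CC(=O)O)C(=O)O",                # aspartic acid
    "CC(C)CC(N)C(=O)O",                 # leucine
    "CCC(C)C(N)C(=O)O",                 # isoleucine
    "CC(C)C(N)C(=O)O",                  # valine
    "NCCCCC(N)C(=O)O",                  # lysine
    "OC(=O)c1cccnc1",                   # nicotinic acid
    "NC(=O)c1ccncc1",                   # isonicotinamide
    "Clc1ccccc1",                       # chlorobenzene
    "Brc1ccccc1",                       # bromobenzene
    "Fc1ccccc1",                        # fluorobenzene
    "CC#N",                             # acetonitrile
    "O=C(N)c1ccccc1",                   # benzamide
    "CNC(=O)c1ccccc1",                  # N-methylbenzamide
    "COC(=O)c1ccccc1",                  # methyl benzoate
    "CC(=O)c1ccccc1",                   # acetophenone
    "OCc1ccccc1",                       # benzyl alcohol
    "O=Cc1ccccc1",                      # benzaldehyde
    "N#Cc1ccccc1",                      # benzonitrile
    "CCOC(=O)C",                        # ethyl acetate
    "CC(C)(C)O",                        # tert-butanol
    "C1CCOC1",                          # tetrahydrofuran
    "C1CCNCC1",                         # piperidine
    "C1CNCCN1",                         # piperazine
    "O=S(=O)(N)c1ccccc1",               # benzenesulfonamide
    "Cc1ccc(cc1)S(=O)(=O)N",            # toluenesulfonamide
)

_DRUG_COLUMNS = ("drug_id", "smiles")
_RESPONSE_COLUMNS = ("drug_id", "cell_id", "ic50")


@dataclass
class DatasetBundle:
    """A validated drug-sensitivity dataset.

    ``drugs`` maps drug id -> SMILES; ``cells`` maps cell id ->
    :class:`~qdinn.encoders.CellLineProfile`; ``responses`` is the list of
    supervised (drug, cell, IC50) records.
    """

    drugs: dict[str, str]
    cells: dict[str, CellLineProfile]
    responses: list[ResponseRecord]

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for i, rec in enumerate(self.responses):
            if rec.drug_id not in self.drugs:
                raise ValueError(
                    f"response {i}: unknown drug_id {rec.drug_id!r}"
                )
            if rec.cell_id not in self.cells:
                raise ValueError(
                    f"response {i}: unknown cell_id {rec.cell_id!r}"
                )
            pair = (rec.drug_id, rec.cell_id)
            if pair in seen:
                raise ValueError(f"response {i}: duplicate pair {pair}")
            seen.add(pair)
        for cid, profile in self.cells.items():
            profile.validate()

    def __len__(self) -> int:
        return len(self.responses)


def pair_count(n_drugs: int, n_cells: int) -> int:
    """Number of drug/cell-line pairs in a full screen: the product."""
    if n_drugs < 1 or n_cells < 1:
        raise ValueError("drug and cell counts must be positive")
    return n_drugs * n_cells


def _require_columns(df: pd.DataFrame, needed, path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def load_bundle(
    drug_csv,
    cell_csv,
    response_csv,
    schema: dict[str, str] | None = None,
) -> DatasetBundle:
    """Read and validate the three CSV tables into a :class:`DatasetBundle`.

    ``schema`` optionally maps the canonical column names (``drug_id``,
    ``smiles``, ``cell_id``, ``ic50``) to the names actually present in the
    files — the adapter hook for real GDSC-style exports. Raw IC50 values
    are normalized on load. Validation failures name the file and row.
    """
    schema = schema or {}

    def col(name: str) -> str:
        return schema.get(name, name)

    drugs_df = pd.read_csv(drug_csv)
    _require_columns(drugs_df, [col(c) for c in _DRUG_COLUMNS], drug_csv)
    drugs = {
        str(row[col("drug_id")]): str(row[col("smiles")])
        for _, row in drugs_df.iterrows()
    }

    cells_df = pd.read_csv(cell_csv)
    cell_id_col = col("cell_id")
    _require_columns(cells_df, [cell_id_col], cell_csv)
    feature_cols = [c for c in cells_df.columns if c != cell_id_col]
    if len(feature_cols) != CELL_PROFILE_DIM:
        raise ValueError(
            f"{cell_csv}: expected {CELL_PROFILE_DIM} mutation columns, "
            f"found {len(feature_cols)}"
        )
    cells: dict[str, CellLineProfile] = {}
    for i, row in cells_df.iterrows():
        cid = str(row[cell_id_col])
        profile = CellLineProfile(
            row[feature_cols].to_numpy(dtype=float), cid
        )
        try:
            profile.validate()
        except ValueError as exc:
            raise ValueError(f"{cell_csv}: row {i}: {exc}") from exc
        cells[cid] = profile

    resp_df = pd.read_csv(response_csv, float_precision="round_trip")
    _require_columns(
        resp_df, [col(c) for c in _RESPONSE_COLUMNS], response_csv
    )
    responses: list[ResponseRecord] = []
    for i, row in resp_df.iterrows():
        did, cid = str(row[col("drug_id")]), str(row[col("cell_id")])
        if did not in drugs:
            raise ValueError(
                f"{response_csv}: row {i}: unknown drug_id {did!r}"
            )
        if cid not in cells:
            raise ValueError(
                f"{response_csv}: row {i}: unknown cell_id {cid!r}"
            )
        ic50 = float(row[col("ic50")])
        if ic50 <= 0:
            raise ValueError(
                f"{response_csv}: row {i}: IC50 must be > 0, got {ic50}"
            )
        responses.append(ResponseRecord(did, cid, ic50))
    bundle = DatasetBundle(drugs, cells, responses)
    bundle.validate()
    return bundle


def write_bundle(bundle: DatasetBundle, out_dir) -> dict[str, Path]:
    """Write a bundle as the three canonical CSVs; returns their paths.

    Round-trips exactly through :func:`load_bundle` (record order and
    float values preserved).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "drugs": out / "drugs.csv",
        "cells": out / "cells.csv",
        "responses": out / "responses.csv",
    }
    pd.DataFrame(
        {"drug_id": list(bundle.drugs), "smiles": list(bundle.drugs.values())}
    ).to_csv(paths["drugs"], index=False)
    feature_names = [f"m{i:03d}" for i in range(CELL_PROFILE_DIM)]
    cells_df = pd.DataFrame(
        [p.mutations.astype(int) for p in bundle.cells.values()],
        columns=feature_names,
    )
    cells_df.insert(0, "cell_id", list(bundle.cells))
    cells_df.to_csv(paths["cells"], index=False)
    pd.DataFrame(
        {
            "drug_id": [r.drug_id for r in bundle.responses],
            "cell_id": [r.cell_id for r in bundle.responses],
            "ic50": [repr(r.ic50_raw) for r in bundle.responses],
        }
    ).to_csv(paths["responses"], index=False)
    return paths


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def generate_fixtures(
    n_drugs: int,
    n_cells: int,
    seed: int = 0,
    noise_sd: float = 0.1,
    mutation_rate: float = 0.1,
) -> DatasetBundle:
    """Seeded synthetic screen with a planted, learnable response signal.

    Drugs are drawn without replacement from :data:`SMILES_POOL`; cell
    profiles are i.i.d. Bernoulli(``mutation_rate``) over the 735 mutation
    slots; raw IC50 values follow the planted log-linear model described in
    the module docstring, over the full cross product of pairs.
    """
    if not 1 <= n_drugs <= len(SMILES_POOL):
        raise ValueError(
            f"n_drugs must be in [1, {len(SMILES_POOL)}] "
            f"(size of the SMILES pool), got {n_drugs}"
        )
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(SMILES_POOL), size=n_drugs, replace=False)
    drugs = {f"D{k:03d}": SMILES_POOL[idx] for k, idx in enumerate(chosen)}
    heavy_atoms = np.array(
        [
            Chem.MolFromSmiles(smiles).GetNumHeavyAtoms()
            for smiles in drugs.values()
        ],
        dtype=float,
    )
    mutations = (
        rng.random((n_cells, CELL_PROFILE_DIM)) < mutation_rate
    ).astype(float)
    cells = {
        f"C{k:04d}": CellLineProfile(mutations[k], f"C{k:04d}")
        for k in range(n_cells)
    }
    z_drug = _standardize(heavy_atoms)
    z_cell = _standardize(mutations[:, :20].sum(axis=1))
    responses: list[ResponseRecord] = []
    for di, drug_id in enumerate(drugs):
        for ci, cell_id in enumerate(cells):
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            log_ic50 = 1.5 * z_cell[ci] + 1.0 * z_drug[di] + eps
            responses.append(
                ResponseRecord(drug_id, cell_id, float(np.exp(log_ic50)))
            )
    bundle = DatasetBundle(drugs, cells, responses)
    bundle.validate()
    return bundle
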