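"""Turn a SMILES string into the model's molecular-graph representation.

Builds the graph for aspirin and prints its dimensions and a few atom
feature rows: each heavy atom becomes a node with a 78-dimensional binary
feature vector (element, degree, hydrogen count, implicit valence, one-hot;
plus an aromaticity flag), and bonds become symmetric adjacency entries.
"""

import numpy as np

from qdinn import smiles_to_graph

graph = smiles_to_graph("CC(=O)Oc1ccccc1C(=O)O", drug_id="aspirin")
graph.validate()

print(f"drug: {graph.drug_id}")
print(f"heavy atoms (nodes): {graph.n_atoms}")
print(f"node-feature matrix: {graph.node_features.shape}")
print(f"bonds (undirected):  {int(graph.adjacency.sum()) // 2}")
print(f"aromatic atoms:      {int(graph.node_features[:, 77].sum())}")
row = graph.node_features[0]
print(f"atom 0 feature row: {int(row.sum())} ones at slots "
      f"{np.flatnonzero(row).tolist()}")
# The slots identify: element one-hot (0-43), degree (44-54),
# attached hydrogens (55-65), implicit valence (66-76), aromatic flag (77).
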