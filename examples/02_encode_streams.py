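"""Inspect the deterministic feature streams for one peptide.

Shows tokenization, the sinusoidal positional encoding, property-table
lookups, amino-acid composition, Gaussian fuzzification and the residue
chain graph that feeds the graph-attention stream.
"""

import numpy as np

from mfpep import (
    FuzzifierParams,
    build_chain_graph,
    encode_aac,
    encode_property_stream,
    gmf_fuzzify,
    load_property_table,
    positional_encoding,
    tokenize,
)

peptide = "KWKLFKKIEK"  # a short cationic peptide
tok = tokenize(peptide, max_len=15)
print("tokens (alphabetical rank, 0 = padding):", tok.tokens.tolist())

pe = positional_encoding(max_len=15, d_model=8)
print("positional encoding row 1 (sin/cos pairs):", np.round(pe[1], 3))

blosum = load_property_table("blosum62")
X = encode_property_stream(tok, blosum)
print("BLOSUM62 row for K (first 5 of 23 scores):", X[0][:5])

aac = encode_aac(peptide)
print("composition (K fraction):", aac[8])  # K is rank 9 -> index 8

pc6 = load_property_table("pc6")
fuzz = gmf_fuzzify(
    encode_property_stream(tok, pc6),
    FuzzifierParams(centers=np.zeros(6), widths=np.ones(6)),
    mask=tok.mask,
)
print("fuzzified PC6 row 0 (memberships in (0,1]):", np.round(fuzz[0], 3))

graph = build_chain_graph(tok)
print(f"chain graph: {graph.n_nodes} nodes, {len(graph.edges)} directed edges")
# Every residue connects to its sequence neighbors, so the adjacency matrix
# is a symmetric path graph over the valid (unpadded) positions.
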