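"""MC-dropout confidence intervals and dominant-atom similarity search.

Uses an untrained model for speed: both computations are architectural and
behave identically (just with arbitrary values) before training.
"""

import numpy as np

from micropka import (
    ModelConfig,
    build_graph,
    build_embedding_index,
    generate_set,
    init_model,
    mc_dropout_predict,
    project_embeddings,
    similar_molecules,
)

state = init_model(ModelConfig(n_layers=4, hidden_dim=32, head_hidden_dims=(16,),
                               dropout_rate=0.2, mode="acidic", seed=5))

# --- 95% interval from 100 stochastic forward passes -----------------------
g = build_graph("OC(=O)CO")  # glycolic acid
u = mc_dropout_predict(state, g, n_samples=100, seed=0)
print(f"macro-pKa = {u.macro_mean:.3f}  95% CI [{u.ci_low:.3f}, {u.ci_high:.3f}] "
      f"({u.n_samples} dropout samples)")
# A wide interval flags molecules the model is unsure about.

# --- neighbor search in dominant-atom embedding space ----------------------
ref = generate_set(40, "acidic", 0.1, seed=21).records
index = build_embedding_index(state, ref)
query = build_graph(ref[3].standardized_smiles)
hits = similar_molecules(index, state, query)  # distance < 0.05, up to 4
print(f"\nquery {ref[3].standardized_smiles}: {len(hits)} neighbor(s)")
for h in hits:
    print(f"  {h['record_id']}  distance {h['distance']:.4f}  "
          f"experimental pKa {h['experimental_pka']:.2f}")

# --- 2-D PCA of the indexed embeddings -------------------------------------
coords, frac = project_embeddings(index.embeddings)
print(f"\nPCA of {len(index)} dominant-atom embeddings: "
      f"explained variance {frac[0]:.2f} + {frac[1]:.2f}")
print(f"first three points: {np.round(coords[:3], 3).tolist()}")
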