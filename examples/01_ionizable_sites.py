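"""Standardize structures and enumerate their ionizable sites.

Acidic sites are non-carbon atoms bearing at least one hydrogen; basic
sites are nitrogens with no positive formal charge.  A neutral N-H can
appear in both sets.
"""

from micropka import build_graph, enumerate_acidic_sites, enumerate_basic_sites, standardize_with_flag

MOLECULES = {
    "sodium acetate": "CC(=O)[O-].[Na+]",
    "glycine (zwitterion)": "[NH3+]CC(=O)[O-]",
    "propane-1,2,3-triamine": "NCC(N)CN",
    "tetramethylammonium": "C[N+](C)(C)C",
    "methanesulfonamide": "CS(N)(=O)=O",
}

for name, raw in MOLECULES.items():
    smiles, flagged = standardize_with_flag(raw)
    g = build_graph(smiles)
    P = sorted(enumerate_acidic_sites(g))
    Q = sorted(enumerate_basic_sites(g))
    note = "  [non-neutralizable charge kept]" if flagged else ""
    print(f"{name:24s} {raw:24s} -> {smiles}{note}")
    print(f"  acidic sites P: {[(i, g.elements[i]) for i in P]}")
    print(f"  basic sites  Q: {[(i, g.elements[i]) for i in Q]}")

# Salt stripping and neutralization happen before site perception, so the
# acetate that arrives as a sodium salt reports the neutral acid's O-H;
# the quaternary ammonium keeps its + charge and therefore has no basic N.
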