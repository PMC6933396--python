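"""Map risk genes onto the global PPI and extract the edge-induced
risk-gene-associated subnetwork."""

import omicsnet as on

cfg = on.default_config(seed=42)
data = on.simulate_all(cfg)
rna_de = on.de_rna(data["rna"], conditions=("control", "glaucoma"))
prot_de = on.de_protein(data["protein"], conditions=("control", "glaucoma"))
risk, _ = on.intersect_risk(rna_de, prot_de)

sub, rep = on.extract_subnetwork(data["ppi"], risk)
print(f"risk genes: {len(risk)}; of these {rep.n_risk_in_network} sit in the "
      f"PPI with at least one partner")
print(f"subnetwork: {rep.n_nodes} nodes, {rep.n_edges} edges "
      f"(every edge touches a risk gene)")
print(f"unmapped risk genes (absent from PPI): {len(rep.unmapped)}")
print(f"isolated risk genes (no partner): {len(rep.isolated)}")
# The subnetwork contains each risk gene's full interaction neighbourhood;
# partner-partner edges are excluded (edge-induced rule), so non-risk nodes
# appear only through their link to a risk gene.
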