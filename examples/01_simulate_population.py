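"""Simulate an autopolyploid pseudo-testcross mapping population.

The informative parent is an aneu-polyploid with 8 homology groups of
13-23 homologues; dominant SD/DD/TD markers are scored in 227 progeny,
with a third of the DArT markers restricted to a 94-progeny panel.
"""

from polylink import SimulationConfig, generate_population

cfg = SimulationConfig(seed=1)
cross = generate_population(cfg)

m = cross.matrix
print(f"markers x progeny : {m.n_markers} x {m.n_progeny}")
print(f"homologues per HG : {cross.config.resolved_homologues()}")
print("dosage truth      :", cross.truth["dosage"].value_counts().to_dict())
print("marker systems    :", m.metadata["system"].value_counts().to_dict())
panel = int(m.metadata["panel_restricted"].sum())
print(f"panel-restricted  : {panel} markers scored on 94 of 227 progeny")
print(f"mean call rate    : {m.call_rate().mean():.3f}")
# dosage counts mirror the mixture in the config; the call rate reflects
# random missingness plus the panel restriction
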