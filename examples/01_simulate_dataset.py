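"""Generate a synthetic cold-stress dataset with two planted motifs.

Builds genes with upstream/body/downstream regions, a differential-
expression table over six cold time points plus three other stresses, GO
annotations and a TFBM library, then prints what was planted where.
"""

from coldcre import PlantedMotif, SimulationConfig, generate_dataset

TIME_POINTS = ("0.5", "1", "3", "6", "16", "24")

config = SimulationConfig(
    n_genes=500,
    upstream_len=300,
    body_len_range=(200, 500),
    downstream_len=200,
    responsive_fraction_per_timepoint=(0.10, 0.12, 0.15, 0.18, 0.22, 0.25),
    planted_motifs=[
        # planted in up-regulated genes at every time point
        PlantedMotif("GATTACA", TIME_POINTS, p_signal=0.8, p_background=0.05),
        # planted only in genes up-regulated at 24 hr
        PlantedMotif("CCACGTG", ("24",), p_signal=0.8, p_background=0.05),
    ],
    seed=42,
)

genes, de, library, truth = generate_dataset(config)

print(f"genes:              {len(genes)}")
print(f"DE table rows:      {len(de)}  (gene x condition x time)")
print(f"TFBM library:       {len(library)} motifs "
      f"({sum(r.family.startswith('FAM_') for r in library)} planted-family, "
      f"{sum(r.family.startswith('DECOY') for r in library)} decoys)")
print(f"planted instances:  {len(truth)}")
print()
print("first planted instance:", truth[0])
print()
print("DE table head:")
print(de.head(8).to_string(index=False))
# Each planted instance overwrites a window of a gene's upstream region at a
# random offset and orientation; the truth ledger above is what recovery
# tests score against.
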