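# Default machine catalogue for the synthetic-plan generator: typical
# dual-photon-energy linac with five electron energies.  Site catalogues
# differ; override with your own file.
machines: [LINAC1, LINAC2]
photon_energies: [6X, 16X]
electron_energies: [6E, 9E, 12E, 16E, 20E]
wedges: [W15, W30, W45, W60]
cones: [A6, A10, A14, A20, A25]
accessories: [BLOCK_TRAY, BOLUS_1CM]
tolerance_tables: [T1, T2, IMRT]
dose_rates: [300.0, 400.0, 600.0]
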