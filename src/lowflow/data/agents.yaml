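# Physical and pharmacologic constants for the volatile anesthetic agents.
#
# Provenance: molecular weights and liquid densities are standard physical
# chemistry values; mac40_pct are the conventional MAC values at age 40 used
# by AIMS age-adjustment; gwp100 values are 100-year global warming
# potentials relative to CO2. The per-agent GWP attribution follows the
# commonly cited literature values (sevoflurane lowest, desflurane highest);
# inventory year and source vary across reports, so these are configuration,
# not asserted physical truth. Override with --agent-constants.
reference_temperature_c: 21.0
agents:
  sevoflurane:
    mw_g_per_mol: 200.05
    density_g_per_ml: 1.52
    mac40_pct: 1.80
    gwp100: 130
  isoflurane:
    mw_g_per_mol: 184.49
    density_g_per_ml: 1.496
    mac40_pct: 1.17
    gwp100: 510
  desflurane:
    mw_g_per_mol: 168.04
    density_g_per_ml: 1.465
    mac40_pct: 6.60
    gwp100: 2540
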