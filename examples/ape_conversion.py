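"""From IRMS atom-percent readings to influx rates.

A short-term labelling assay measures the ¹⁵N enrichment of root tissue
after a 10-minute incubation in a 99.9 atom % ¹⁵N feeding solution.  The
enrichment, together with the tissue's total N and the incubation time,
converts to an influx rate in μmol N per g dry weight per hour.
"""

from ninflux import ape_to_influx

ape_source = 99.9        # atom % 15N of the (15NH4)2SO4 feeding solution
n_total = 1500.0         # μmol N per g DW of root tissue
duration_h = 10.0 / 60.0 # 10-minute incubation, in hours

print("APE_sample (atom %)   influx (μmol/g DW/h)")
for ape_sample in (0.0, 0.005, 0.01, 0.02, 0.05):
    v = ape_to_influx(ape_sample, ape_source, n_total, duration_h)
    print(f"{ape_sample:>10.3f} {v:>20.3f}")

print("\nEach 0.01 atom % of excess 15N in this tissue corresponds to about "
      f"{ape_to_influx(0.01, ape_source, n_total, duration_h):.2f} μmol/g DW/h "
      "of influx.\nThe conversion is the minimal isotope-dilution formula "
      "(ape_sample/ape_source) * N_total / t;\nnatural-abundance background "
      "subtraction is up to the caller.")
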