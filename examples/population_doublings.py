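"""Cumulative population doublings from serial-passage cell counts.

Each passage contributes PD = 3.32*(log10(yield) - log10(inoculum)),
chained within a lineage so a culture's replicative history accumulates
across passages.
"""

import io

import pandas as pd

import pmdclock as pc

sheet_csv = io.StringIO(
    "sample_id,lineage,passage,cell_yield,inoculum,inoculum_pd\n"
    "fib_p1,fibroblast,1,4.1e6,1.0e6,0\n"
    "fib_p2,fibroblast,2,3.7e6,1.0e6,0\n"
    "fib_p3,fibroblast,3,2.2e6,1.0e6,0\n"
)
sheet = pd.read_csv(sheet_csv)
sheet["cum_pd"] = pc.cumulative_pds(sheet)
print(sheet[["sample_id", "cell_yield", "cum_pd"]].round(2).to_string(index=False))

single = pc.compute_population_doublings(1e7, 1e6, 0.0)
print(f"\none tenfold expansion = {single} PDs (the formula's constant)")
print(
    "cum_pd is the culture's division count so far: the quantity methylation "
    "erosion tracks. Note the slowing growth toward senescence (smaller "
    "yields -> smaller PD increments)."
)
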