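"""Derive rate/yield changes between control and stressed chemostats.

Loads the glucose-limited anaerobic chemostat measurements (control vs
7 mM p-coumaric acid) and prints the percent and log2 changes of each
physiological parameter. Positive percentages mean the stressed culture
runs the process faster (or yields more) than the control.
"""

from pathlib import Path

from stressweave import io as swio
from stressweave import physiology

table = swio.read_physiology(Path(__file__).parents[1] / "data" / "chemostat_physiology.csv")
comparison = physiology.compare_conditions(table)
print(comparison.to_string(index=False))

eth = comparison.set_index("parameter").loc["q_ethanol"]
print(
    f"\nSpecific ethanol production rose {eth['percent_change']:+.0f}% "
    f"(log2 fold change {eth['log2_fold_change']:.3f}) under stress, while "
    "biomass yield fell: carbon is diverted from growth to fermentation."
)
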