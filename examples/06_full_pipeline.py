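"""Run the whole pipeline from a configuration dict to CSV artifacts.

Uses the bundled demo configuration (12 synthetic years, one coupled
heatwave and one coupled cold-spell) and writes every stage's outputs —
series, climatologies, event tables, season classifications, trends and MLD
records — under ./scratch/pipeline_demo.
"""

from pathlib import Path

import pandas as pd

from mhwbloom import default_config, run_pipeline

out_dir = Path("scratch/pipeline_demo")
artifacts = run_pipeline(default_config(), out_dir)

print("artifacts written:")
for name, path in artifacts.items():
    print(f"  {name:20s} {path}")

cases = pd.read_csv(artifacts["cases"])
print("\nseason classifications:")
print(cases[["season_year", "n_mhw", "n_mcs", "n_hchla", "n_lchla",
             "classification"]].to_string(index=False))
print()
print("Rerunning with the same configuration reproduces every CSV byte for")
print("byte; the injected 2005/2008 episodes classify as 'expected'.")
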