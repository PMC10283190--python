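"""Assemble the comparison report from the fitted models.

Prints the model-comparison table (-2 Log LL, LOOIC, WAIC, ranked by
LOOIC), the variance partitioning of the selected model, and any
convergence flags — the decision layer of the analysis.

    python analysis/04_report.py
"""

import json
from pathlib import Path

import pandas as pd

fits = Path("results/fits")
print((fits / "comparison.txt").read_text())

manifest = json.loads((fits / "manifest.json").read_text())
winner = manifest["selected_model"]
vpc_path = fits / f"vpc_{winner}.csv"
if vpc_path.exists():
    print(f"\nvariance partitioning ({winner}, latent scale):")
    print(pd.read_csv(vpc_path, index_col=0).round(3).to_string())

flagged = manifest.get("convergence_flagged", [])
print("\nconvergence:", "all families clean" if not flagged
      else f"flags in {flagged} (see diagnostics_*.csv)")
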