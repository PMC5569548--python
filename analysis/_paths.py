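"""Shared locations for the staged analysis scripts.

Bulky intermediates (PLINK files, full association tables, matrices) live
under scratch/; each numbered script writes its small summary tables under
results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
INTERMEDIATE = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

TRAITS = ("sc420", "afc")  # trait with planted QTL, pure-polygenic trait

for _d in (DATA, INTERMEDIATE, RESULTS):
    _d.mkdir(parents=True, exist_ok=True)
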