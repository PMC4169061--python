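"""Shared configuration for the numbered analysis drivers.

One reference synthetic cohort (seed 42) flows through every stage;
drivers read the previous stage's outputs from results/ and append their
own. Run the scripts in order from the repository root:

    python analysis/01_simulate.py
    python analysis/02_metabolite_pca.py
    ...
"""

from pathlib import Path

from micronet.simulate import SimConfig

SEED = 42
RESULTS = Path("results/analysis")
INPUTS = RESULTS / "inputs"

STUDY_CONFIG = SimConfig(seed=SEED)

# gene-level Monte-Carlo schedule: enough resolution for q<0.1 over ~1,000
# genes without the full-scale final stage
GENE_STAGES = (1_000, 10_000, 100_000)
SPINS = 25
RESTARTS = 3
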