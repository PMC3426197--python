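"""Selection stability under swapping the class labels.

The RSVM criterion w_j * (m_j+ - m_j-) should in exact arithmetic be
invariant to negating every class label, yet solver asymmetries can make
the selected sets drift; the SV-restricted t criterion is symmetric by
construction.  Each run draws one dataset, runs the elimination under both
label orientations, and compares the final gene sets by their Jaccard
coefficient.
"""
from svmt import SIMULATION_LADDER, label_switch_experiment, scenario_config

N_RUNS = 5  # reduced from the canonical 200 for a quick demonstration
LEVEL = 50

config = scenario_config(1, n_runs=N_RUNS, base_seed=0)
for method in ("svmt", "rsvm"):
    result = label_switch_experiment(
        config, method, ladder=SIMULATION_LADDER, final_level=LEVEL
    )
    jac = result.jaccard_per_run
    freq = result.frequency_frame()
    informative = freq.gene_id.str[1:].astype(int) <= 300
    print(
        f"{method:>6}: mean Jaccard {jac.mean():.3f} (min {jac.min():.3f}); "
        f"informative-gene share of selections "
        f"{freq.freq_original[informative].sum() / freq.freq_original.sum():.2%}"
    )
print(
    "\nJaccard 1.0 means the same 50 genes are selected whichever class is"
    "\ncalled +1; values below 1 reveal label-assignment sensitivity."
)
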