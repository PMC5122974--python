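"""End-to-end synthetic population: place model neurons across a pinwheel
map, run the stimulus battery through the EN circuit, fit every site, and
correlate response properties with local map homogeneity.
"""
from encortex.experiments import ExperimentConfig, run_full_population

report = run_full_population(ExperimentConfig(seed=7))
print(f"{report['n_sites']} sites across LHI strata\n")
print(f"{'pair':<24}{'Pearson r':>10}{'Spearman':>10}{'p':>12}")
for name, c in report["correlations"].items():
    print(f"{name:<24}{c['pearson_r']:>+10.3f}{c['spearman']:>+10.3f}"
          f"{c['p']:>12.2e}")

print("\nnegative LHI-HWHH: tuning sharpens toward iso-orientation domains;"
      "\npositive LHI-SI and LHI-NLI: suppression and contrast saturation"
      "\nstrengthen there; negative LHI-octo: multi-orientation patterns"
      "\ndrive pinwheel neighbourhoods best.")
print("\nsign checks:", "all passed" if report["passed"]
      else f"failing: {report['failures']}")
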