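"""Run the KCCU and CCU co-association tests on one simulated gene pair.

Simulates a case-control dataset with an interaction odds ratio of 1.4
(causal SNPs removed), then asks whether the joint correlation structure of
the two genes differs between cases and controls.
"""

from kccu import DiseaseModel, KernelSpec, co_association_test, default_pools, simulate_case_control

pool1, pool2 = default_pools()
dataset = simulate_case_control(
    pool1, pool2, DiseaseModel(theta=1.4), n_cases=1000, n_controls=1000, seed=7
)
split = dataset.to_split()

for method, spec in (("kccu", KernelSpec(sigma=0.5)), ("ccu", None)):
    res = co_association_test(split, method, spec, B=100, seed=1)
    print(
        f"{method}: kr_cases={res.kr_cases:.4f} kr_controls={res.kr_controls:.4f} "
        f"U={res.U:+.3f} p={res.p_value:.4f}"
    )

print(
    "\nU compares the Fisher-transformed (kernel) canonical correlation of the\n"
    "two genes between strata; a large |U| (small p) says the genes are more\n"
    "strongly co-associated in one stratum - here induced by the theta=1.4\n"
    "interaction at the removed causal SNPs, leaking through LD."
)
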