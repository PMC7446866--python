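"""Reference summary counts from a statewide linked-records homelessness study.

These are the printed summary numbers of a Massachusetts 2011-2015 linked
administrative-records analysis of homelessness classification and fatal
opioid overdose: cohort and stratum sizes, validation-sample performance
percentages, and the weighted group/death counts behind the published
rate-ratio table. They serve as worked-example inputs for the arithmetic
operations in this package (rates, rate ratios, balanced accuracy, stratified
allocation); none of the package's model code depends on them.
"""

from types import MappingProxyType

#: analytic cohort: unique persons with an APCD record plus one other source
COHORT_N = 5_050_639

#: persons meeting >=1 of the four known-case criteria
KNOWN_HOMELESS_N = 41_457

#: known-case counts by contributing source
KNOWN_BY_SOURCE = MappingProxyType(
    {"apcd": 23_239, "casemix": 21_722, "dmh": 300, "matris": 3_237, "pmp": 6_704}
)

#: known cases flagged by two or more sources
MULTI_SOURCE_N = 13_745

#: outcome strata for the 75/25 development/validation split
STRATA_SIZES = (KNOWN_HOMELESS_N, COHORT_N - KNOWN_HOMELESS_N)

#: printed development-sample size (75% of the cohort, allocated per stratum)
DEVELOPMENT_N = 3_787_980

#: validation sample (the remaining 25%)
VALIDATION_N = 1_262_659

#: fatal opioid overdoses observed in the validation sample
VALIDATION_DEATHS = 1_265

#: persons flagged homeless at the 0.5 probability threshold
VALIDATION_FLAGGED_N = 69_675

#: validation-sample performance summary (percent, except AUC)
PERFORMANCE = MappingProxyType(
    {"auc": 0.94, "sensitivity": 77.8, "specificity": 95.1, "ppv": 11.7, "npv": 99.8}
)

#: known-case prevalence in the cohort, percent
OBSERVED_PREVALENCE_PCT = 0.82

#: rate-table rows: (n_homeless, deaths_homeless, n_nonhomeless, deaths_nonhomeless)
RATE_TABLE = MappingProxyType(
    {
        "threshold_binary": (VALIDATION_FLAGGED_N, 724, 1_192_443, 541),
        "known_override": (169_378, 743, 1_093_281, 522),
        "known_and_zeroed": (55_430, 618, 1_207_229, 647),
    }
)
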