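"""Comparative-Ct (delta-delta-Ct) relative quantification of a qPCR panel.

Each sample's target Ct is referenced to a housekeeping gene and to the
control-group mean; fold change is 2^(-ddCt), so one cycle earlier means a
doubling of expression relative to control.
"""

import pandas as pd

from ihtseq import ddct_fold

ct = pd.DataFrame(
    [
        ("ctrl_1", "control", "TNF", 26.1), ("ctrl_1", "control", "ACTB", 17.9),
        ("ctrl_2", "control", "TNF", 25.8), ("ctrl_2", "control", "ACTB", 17.7),
        ("ctrl_3", "control", "TNF", 26.0), ("ctrl_3", "control", "ACTB", 18.1),
        ("fib_1", "Fib", "TNF", 23.6), ("fib_1", "Fib", "ACTB", 18.0),
        ("fib_2", "Fib", "TNF", 23.9), ("fib_2", "Fib", "ACTB", 17.8),
        ("fib_3", "Fib", "TNF", 23.4), ("fib_3", "Fib", "ACTB", 18.2),
    ],
    columns=["sample_id", "group", "gene", "ct"],
)

folds = ddct_fold(ct, target_gene="TNF", reference_gene="ACTB", calibrator_group="control")
print(folds.round(3).to_string(index=False))
print("\ncontrol folds center on 1 by construction; treated folds are the "
      "expression of TNF relative to the control group mean")
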