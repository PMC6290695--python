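"""Sobol sensitivity indices of the Ishigami function with bootstrap errors.

The Ishigami function is a standard benchmark with a known variance
decomposition; the first-order indices of its three inputs are about 31.4%,
44.2% and 0%, and input 3 acts only through its interaction with input 1
(total index about 24.4%).
"""

import numpy as np

from isrsim import (ParameterSpace, bootstrap_estimate, build_design,
                    first_order_index, total_index)

a, b = 7.0, 0.1
space = ParameterSpace(tuple((f"x{i}", -np.pi, np.pi) for i in (1, 2, 3)))
design = build_design(space, M=20_000, seed_root=0)


def ishigami(x):
    return (np.sin(x[:, 0]) + a * np.sin(x[:, 1]) ** 2
            + b * x[:, 2] ** 4 * np.sin(x[:, 0]))


cols = list(space.names)
blocks = {"A": ishigami(design.block_rows("A")[cols].to_numpy())}
for i in range(3):
    blocks[f"FO{i}"] = ishigami(design.block_rows("FO", i)[cols].to_numpy())
    blocks[f"TO{i}"] = ishigami(design.block_rows("TO", i)[cols].to_numpy())

rng = np.random.default_rng(0)
print("input   S_i (%)            ST_i (%)")
for i in range(3):
    (_, s_mean), (_, s_err) = bootstrap_estimate(
        {"A": blocks["A"], "F": blocks[f"FO{i}"]},
        lambda blk: np.array(first_order_index(blk["A"], blk["F"])),
        K=300, rng=rng)
    (_, st_mean), (_, st_err) = bootstrap_estimate(
        {"A": blocks["A"], "T": blocks[f"TO{i}"]},
        lambda blk: np.array(total_index(blk["A"], blk["T"])),
        K=300, rng=rng)
    print(f"x{i + 1}      {s_mean:5.1f} +- {s_err:4.2f}      "
          f"{st_mean:5.1f} +- {st_err:4.2f}")
print("\nExpected: S = (31.4, 44.2, 0.0); ST_3 = 24.4 (pure interaction).")
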