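#!/usr/bin/env python
"""Confirmation + control-exclusion funnel replay.

Of 208 selected candidates, 133 were technically re-tested (126
confirmed) and 8 were detected in control pools; removing the 7
confirmation failures and the 8 control positives leaves 193 candidate
variants (118 validated, 75 not evaluated).
"""

from exomesieve import VariantKey, apply_confirmation_and_controls
from exomesieve.fixtures import FUNNEL_COUNTS


def main() -> None:
    n = FUNNEL_COUNTS
    keys = [VariantKey("c", i + 1, "A", "G") for i in range(n["selected"])]
    result = apply_confirmation_and_controls(
        set(keys),
        tested=set(keys[:n["tested"]]),
        confirmed=set(keys[:n["confirmed"]]),
        control_positive=set(keys[:n["control_positive"]]),
    )
    print(f"selected:            {result.n_input}")
    print(f"tested / confirmed:  {result.n_tested} / {result.n_confirmed}")
    print(f"confirmation failed: {result.n_confirmation_failed}")
    print(f"control positive:    {n['control_positive']}")
    print(f"surviving:           {result.n_surviving} "
          f"({result.n_surviving_validated} validated, "
          f"{result.n_surviving_untested} not evaluated)")


if __name__ == "__main__":
    main()
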