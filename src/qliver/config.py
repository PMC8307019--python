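"""Centralised clinical thresholds and acquisition constants.

All grade boundaries used anywhere in the package live here so that a
single override propagates to grading, warnings and reports.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Base inter-echo spacing of the multi-echo gradient-echo protocol, by
#: field strength.  Water and fat protons return to phase alignment every
#: other echo, so odd multiples of the base spacing are opposed-phase and
#: even multiples are in-phase.
BASE_ECHO_SPACING_MS = {1.5: 2.4, 3.0: 1.2}

#: Tolerance when matching a nominal TE to a multiple of the base spacing
#: (DICOM headers round echo times).
TE_TOLERANCE_MS = 0.1

SUPPORTED_FIELDS_T = (1.5, 3.0)


@dataclass(frozen=True)
class Thresholds:
    """Grade boundaries for steatosis (fat fraction, %) and hepatic iron
    overload (liver iron concentration, µmol/g dry weight).

    Steatosis: none below ``ff_mild``; mild in [ff_mild, ff_moderate);
    moderate in [ff_moderate, ff_severe]; severe strictly above
    ``ff_severe``.  Iron: none below ``lic_mild``; mild in
    [lic_mild, lic_severe]; severe strictly above ``lic_severe``.
    """

    ff_mild: float = 6.4
    ff_moderate: float = 17.4
    ff_severe: float = 22.1
    lic_mild: float = 36.0
    lic_severe: float = 80.0


DEFAULT_THRESHOLDS = Thresholds()
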