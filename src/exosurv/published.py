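"""Reference parameter values for human beta-cell exocytosis.

Point estimates obtained from TIRF recordings of insulin-granule exocytosis
in beta-cells from healthy and diabetic human donors, under a protocol of ten
1-s high-K+ depolarizations at 10-s spacing.  They serve as realistic ground
truth for the synthetic-data generator and as inputs to the granule-count
arithmetic in :mod:`exosurv.reporting`.
"""

from __future__ import annotations

from .model import FrailtyParams, PoissonParams
import math

#: Three-branch piecewise-hazard estimates (rates in s^-1): first pulse
#: 0.0176, later pulses 0.0013, between pulses 0.0003; log hazard ratios of
#: diabetes -1.48, -0.09, 0.98 for the same branches.
POISSON_ESTIMATES = PoissonParams(
    alpha=(math.log(0.0176), math.log(0.0013), math.log(0.0003)),
    beta=(-1.48, -0.09, 0.98),
)

#: Discrete-frailty (IRP) model estimates: pulse rate 0.00117 s^-1, between
#: rate 0.00014 s^-1, diabetes effect between pulses beta2 = 1.43, IRP rate
#: multiplier eta = 499.5, IRP fractions pi0 = 2.6% (healthy), pi1 = 1.0%
#: (diabetic).
FRAILTY_ESTIMATES = FrailtyParams(
    alpha1=math.log(0.00117),
    alpha2=math.log(0.00014),
    beta2=1.43,
    eta=499.5,
    pi0=0.026,
    pi1=0.010,
)

#: Whole-cell membrane capacitance of a human beta-cell, picofarads.
CELL_CAPACITANCE_PF = 10.0
#: Specific membrane capacitance, femtofarads per square micrometre.
SPECIFIC_CAPACITANCE_FF_PER_UM2 = 10.0
#: Density of docked granules on the plasma membrane, per square micrometre.
DOCKED_GRANULE_DENSITY_PER_UM2 = 0.8

#: Study design: clusters (cells) per donor condition.
N_CELLS_HEALTHY = 11
N_CELLS_DIABETIC = 8
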