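"""Physical constants in the unit system used across the package.

Geometry is expressed in millimetres, time in seconds, frequency in Hz.
"""

#: Speed of light in free space, m/s.
C0_M = 299_792_458.0

#: Speed of light in free space, mm/s (geometry is in millimetres).
C0_MM = C0_M * 1e3

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12

#: Vacuum permeability, H/m.
MU0 = 1.25663706212e-6

#: Free-space wave impedance, ohms.
ETA0 = 376.730313668
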