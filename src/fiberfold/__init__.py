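"""fiberfold: quantitative solid-state structural analysis of protein fibers.

Analysis stages for establishing an alpha-helix to beta-sheet conversion in
fibrous protein samples: FTIR amide I band deconvolution, WAXS fiber
diffraction reduction, chemical-shift secondary-structure classification,
sequence fibrillation-hotspot calling and CD fraction unmixing, each paired
with a synthetic-data generator carrying known ground truth.
"""

from . import cd, ftir, nmr, seqstruct, spectrum, synthdata, waxs
from .spectrum import Spectrum1D, read_spectrum, write_spectrum

__version__ = "0.1.0"

__all__ = [
    "cd", "ftir", "nmr", "report", "seqstruct", "spectrum", "synthdata",
    "waxs", "Spectrum1D", "read_spectrum", "write_spectrum", "__version__",
]


def __getattr__(name):
    # report imports most other modules; load it lazily to keep import light
    if name == "report":
        import importlib
        return importlib.import_module("fiberfold.report")
    raise AttributeError(f"module 'fiberfold' has no attribute {name!r}")
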