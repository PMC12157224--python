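import pytest
from hypothesis import HealthCheck, settings

from addsim.synthetic_fixtures import study_fixtures, study_molecules

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


# printed reference characteristics of the study compounds:
# cid -> (formula, mol weight, atom counts, functional groups, rings, aromatic)
TABLE_CENSUS = {
    4632: ("C14H12O3", 228.24, dict(C=14, H=12, O=3),
           dict(ROH=1, RCOR=1, ROR=1), 2, 2),
    8569: ("C14H12O4", 244.24, dict(C=14, H=12, O=4),
           dict(ROH=2, RCOR=1, ROR=1), 2, 2),
    8571: ("C13H10O5", 246.22, dict(C=13, H=10, O=5),
           dict(ROH=4, RCOR=1), 2, 2),
    8572: ("C13H10O3", 214.21, dict(C=13, H=10, O=3),
           dict(ROH=2, RCOR=1), 2, 2),
    11178: ("C36H70O4Zn", 632.35, dict(C=36, H=70, O=4, Zn=1),
            dict(RCOOH=2), 0, 0),
    12738: ("C42H82O4S", 683.16, dict(C=42, H=82, O=4, S=1),
            dict(RCOOR=2), 0, 0),
    15797: ("C21H26O3", 326.42, dict(C=21, H=26, O=3),
            dict(ROH=1, RCOR=1, ROR=1), 2, 2),
    16386: ("C35H62O3", 530.86, dict(C=35, H=62, O=3),
            dict(ROH=1, RCOOR=1), 1, 1),
    17113: ("C13H11N3O", 225.24, dict(C=13, H=11, N=3, O=1),
            dict(ROH=1), 3, 3),
    24667: ("C22H32O4", 360.48, dict(C=22, H=32, O=4),
            dict(ROH=2, ROR=2), 2, 2),
    31250: ("C30H58O4S", 514.84, dict(C=30, H=58, O=4, S=1),
            dict(RCOOR=2), 0, 0),
    31404: ("C15H24O", 220.35, dict(C=15, H=24, O=1), dict(ROH=1), 1, 1),
    62485: ("C20H25N3O", 323.43, dict(C=20, H=25, N=3, O=1),
            dict(ROH=1), 3, 3),
    62531: ("C17H18ClN3O", 315.79, dict(C=17, H=18, Cl=1, N=3, O=1),
            dict(ROH=1), 3, 3),
    64819: ("C73H108O12", 1177.63, dict(C=73, H=108, O=12),
            dict(ROH=4, RCOOR=4), 4, 4),
    70355: ("C13H16O2", 204.26, dict(C=13, H=16, O=2),
            dict(ROH=1, RCOR=1), 2, 1),
    77470: ("C20H24ClN3O", 357.88, dict(C=20, H=24, Cl=1, N=3, O=1),
            dict(ROH=1), 3, 3),
    90571: ("C16H16O3", 256.29, dict(C=16, H=16, O=3),
            dict(RCOR=1, ROR=2), 2, 2),
    91601: ("C42H63O3P", 646.92, dict(C=42, H=63, O=3, P=1), dict(), 3, 3),
    93481: ("C20H23N3O3", 353.41, dict(C=20, H=23, N=3, O=3),
            dict(ROH=1, RCOOR=1), 3, 3),
    112412: ("C30H29N3O", 447.57, dict(C=30, H=29, N=3, O=1),
             dict(ROH=1), 5, 5),
    172473: ("C15H29NO6", 319.39, dict(C=15, H=29, N=1, O=6),
             dict(R3N=1, ROH=2, RCOOH=2), 1, 0),
    3601357: ("C35H54O6P2", 632.75, dict(C=35, H=54, O=6, P=2),
              dict(), 4, 2),
    4992761: ("C27H27N3O2", 425.52, dict(C=27, H=27, N=3, O=2),
              dict(ROH=1, ROR=1), 4, 4),
}


@pytest.fixture(scope="session")
def study():
    """Parsed study compounds keyed by CID."""
    return study_molecules()


@pytest.fixture(scope="session")
def fixtures():
    return study_fixtures()
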