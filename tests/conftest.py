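import datetime as dt

import pytest

from orphanbonds.focal_data_io import FocalFollow, InteractionEvent
from orphanbonds.population_model import ElephantRecord, Registry


@pytest.fixture
def window():
    # two-year study window, midpoint 2014.0
    return (2013.0, 2015.0)


@pytest.fixture
def registry():
    """One core group with a full kin structure, plus a second group and a bull.

    G1: grandmother GM (b. 1970, matriarch), her daughters MOM (b. 1988) and
    AUNT (b. 1990); MOM's daughters FOC (b. 2004, the focal) and SIS (b. 2001);
    AUNT's calf CALF (b. mid-2014). G2: OLDF (b. 1980). BULL (b. 1995) is a
    dispersed male attached to G2. MOM2/FOC2 in G1 give a second, orphaned
    focal (MOM2 died 2012).
    """
    return Registry([
        ElephantRecord("GM", "F", 1970.0, None, "G1"),
        ElephantRecord("MOM", "F", 1988.0, "GM", "G1"),
        ElephantRecord("AUNT", "F", 1990.0, "GM", "G1"),
        ElephantRecord("FOC", "F", 2004.0, "MOM", "G1"),
        ElephantRecord("SIS", "F", 2001.0, "MOM", "G1"),
        ElephantRecord("CALF", "M", 2014.5, "AUNT", "G1"),
        ElephantRecord("MOM2", "F", 1986.0, "GM", "G1", death_year=2012.0),
        ElephantRecord("FOC2", "F", 2003.0, "MOM2", "G1"),
        ElephantRecord("OLDF", "F", 1980.0, None, "G2"),
        ElephantRecord("BULL", "M", 1995.0, None, "G2", dispersed_from_natal=True),
    ])


@pytest.fixture
def follows():
    """Two 30-minute feeding follows of FOC and one of FOC2, one resting follow."""
    return [
        FocalFollow("f1", "FOC", dt.date(2013, 6, 1), "feeding", 30.0,
                    frozenset({"SIS", "MOM", "BULL"})),
        FocalFollow("f2", "FOC", dt.date(2013, 6, 2), "feeding", 30.0,
                    frozenset({"SIS", "GM"})),
        FocalFollow("f3", "FOC2", dt.date(2014, 6, 1), "feeding", 20.0,
                    frozenset({"GM", "AUNT"})),
        FocalFollow("r1", "FOC", dt.date(2013, 6, 1), "resting", 10.0,
                    frozenset({"SIS"})),
    ]


@pytest.fixture
def interactions():
    return [
        InteractionEvent("f1", "SIS", "greeting"),
        InteractionEvent("f2", "SIS", "trunk_touch"),
        InteractionEvent("f2", "SIS", "other"),        # non-affiliative, filtered
        InteractionEvent("f1", "MOM", "bodily_contact"),
        InteractionEvent("f3", "GM", "play"),
        InteractionEvent("r1", "SIS", "trunk_to_mouth"),
    ]
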