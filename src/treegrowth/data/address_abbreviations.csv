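abbreviation,expansion
ST,STREET
STR,STREET
AVE,AVENUE
AV,AVENUE
RD,ROAD
DR,DRIVE
BLVD,BOULEVARD
PL,PLACE
LN,LANE
CT,COURT
TER,TERRACE
TERR,TERRACE
PKWY,PARKWAY
PKY,PARKWAY
HWY,HIGHWAY
EXPY,EXPRESSWAY
SQ,SQUARE
CIR,CIRCLE
BCH,BEACH
N,NORTH
S,SOUTH
E,EAST
W,WEST
NE,NORTHEAST
NW,NORTHWEST
SE,SOUTHEAST
SW,SOUTHWEST
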