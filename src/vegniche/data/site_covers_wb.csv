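# Published relative cover fractions at the WB site:
# observed releve, uncalibrated (blind) model run, calibrated model run.
# Values are rounded to two decimals; absent species have no row.
species,observed,blind,calibrated
Abies balsamea,0.00,0.01,0.01
Acer pensylvanicum,0.14,0.08,0.15
Acer rubrum,0.03,0.10,0.04
Acer saccharum,0.14,0.03,0.15
Aralia nudicaulis,0.03,0.01,0.01
Betula alleghaniensis,0.04,0.01,0.01
Clintonia borealis,0.00,0.02,0.02
Coptis trifolia,0.00,0.00,0.00
Cornus alternifolia,0.00,0.00,0.00
Cornus canadensis,0.00,0.00,0.00
Dennstaedtia punctilobula,0.00,0.04,0.05
Dryopteris campyloptera,0.16,0.00,0.19
Fagus grandifolia,0.18,0.08,0.18
Fraxinus americana,0.00,0.04,0.00
Gymnocarpium dryopteris,0.03,0.00,0.00
Lonicera canadensis,0.00,0.00,0.00
Maianthemum canadense,0.01,0.00,0.00
Medeola virginiana,0.00,0.00,0.00
Osmunda claytoniana,0.00,0.19,0.01
Phegopteris connectilis,0.00,0.00,0.00
Picea rubens,0.04,0.01,0.01
Polygonatum pubescens,0.00,0.00,0.00
Polygonum convolvulus,0.00,0.00,0.00
Polystichum acrostichoides,0.00,0.00,0.00
Prunus serotina,0.00,0.06,0.00
Quercus rubra,0.00,0.06,0.00
Sorbus americana,0.00,0.05,0.00
Thelypteris noveboracensis,0.03,0.00,0.00
Trientalis borealis,0.01,0.00,0.00
Trillium spp,0.00,0.00,0.00
Uvularia sessilifolia,0.07,0.02,0.04
Viburnum acerifolium,0.00,0.00,0.00
Viburnum lantanoides,0.07,0.14,0.07
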