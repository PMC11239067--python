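variant,canonical,scientific
london planetree,London Planetree,Platanus x acerifolia
london plane tree,London Planetree,Platanus x acerifolia
london plane,London Planetree,Platanus x acerifolia
planetree,London Planetree,Platanus x acerifolia
honeylocust,Honeylocust,Gleditsia triacanthos
honey locust,Honeylocust,Gleditsia triacanthos
callery pear,Callery Pear,Pyrus calleryana
bradford pear,Callery Pear,Pyrus calleryana
norway maple,Norway Maple,Acer platanoides
pin oak,Pin Oak,Quercus palustris
littleleaf linden,Littleleaf Linden,Tilia cordata
little leaf linden,Littleleaf Linden,Tilia cordata
little-leaf linden,Littleleaf Linden,Tilia cordata
ginkgo,Ginkgo,Ginkgo biloba
gingko,Ginkgo,Ginkgo biloba
maidenhair tree,Ginkgo,Ginkgo biloba
green ash,Green Ash,Fraxinus pennsylvanica
red maple,Red Maple,Acer rubrum
silver maple,Silver Maple,Acer saccharinum
japanese zelkova,Japanese Zelkova,Zelkova serrata
zelkova,Japanese Zelkova,Zelkova serrata
sweetgum,Sweetgum,Liquidambar styraciflua
sweet gum,Sweetgum,Liquidambar styraciflua
silver linden,Silver Linden,Tilia tomentosa
northern red oak,Northern Red Oak,Quercus rubra
red oak,Northern Red Oak,Quercus rubra
american linden,American Linden,Tilia americana
basswood,American Linden,Tilia americana
american basswood,American Linden,Tilia americana
willow oak,Willow Oak,Quercus phellos
sophora,Sophora,Styphnolobium japonicum
japanese pagoda tree,Sophora,Styphnolobium japonicum
cherry,Cherry,Prunus spp.
crabapple,Crabapple,Malus spp.
crab apple,Crabapple,Malus spp.
hedge maple,Hedge Maple,Acer campestre
white oak,White Oak,Quercus alba
american elm,American Elm,Ulmus americana
elm,American Elm,Ulmus americana
black locust,Black Locust,Robinia pseudoacacia

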