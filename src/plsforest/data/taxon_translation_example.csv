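vernacular,taxon_std
ash,Ash
b. ash,Ash
w. ash,Ash
basswood,Basswood
lynn,Basswood
beech,Beech
birch,Birch
w. birch,Birch
y. birch,Birch
gum,Black gum/sweet gum
sweet gum,Black gum/sweet gum
black gum,Black gum/sweet gum
cedar,Cedar/juniper
juniper,Cedar/juniper
w. cedar,Cedar/juniper
cherry,Cherry
b. cherry,Cherry
dogwood,Dogwood
elm,Elm
r. elm,Elm
w. elm,Elm
fir,Fir
balsam,Fir
hemlock,Hemlock
hickory,Hickory
shagbark,Hickory
ironwood,Ironwood
hornbeam,Ironwood
maple,Maple
s. maple,Maple
sug. maple,Maple
r. maple,Maple
oak,Oak
w. oak,Oak
b. oak,Oak
r. oak,Oak
bur oak,Oak
pine,Pine
w. pine,Pine
n. pine,Pine
j. pine,Pine
poplar,Poplar/tulip poplar
aspen,Poplar/tulip poplar
tulip,Poplar/tulip poplar
whitewood,Poplar/tulip poplar
spruce,Spruce
b. spruce,Spruce
tamarack,Tamarack
larch,Tamarack
walnut,Walnut
b. walnut,Walnut
butternut,Walnut
box elder,Other hardwood
locust,Other hardwood
sycamore,Other hardwood
willow,Other hardwood
mulberry,Other hardwood
hackberry,Other hardwood
no tree,no-tree
post,no-tree
stake,no-tree
water,water
lake,water
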